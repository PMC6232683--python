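"""Bounded-length simple-path enumeration and the decay-weighted score.

The association confidence of a pair (l, d) is a sum over all simple
(noncyclic) paths connecting them with at most tau edges:

    score(l, d) = sum_w (prod of edge weights along p_w) * F_decay(p_w)

Longer paths carry weaker evidence, so the default decay is geometric in the
number of edges, F_decay(p) = alpha**(-len(p)) with alpha = 2.26.  An
alternative form that exponentiates the weight product itself,
(prod w)**(alpha * len), is available via ``NetworkConfig.decay_form``.

Enumeration is an explicit depth-first search that prunes at depth tau and
never revisits a node on the current stack.  ``score_all`` amortizes one DFS
per lncRNA, accumulating the score contribution at every disease node the
walk touches, which is what makes full leave-one-out evaluation tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import AssociationDataset
from .network import HeteroNetwork, NetworkConfig, dnode, lnode

__all__ = ["Path", "PairScore", "enumerate_paths", "path_score",
           "score_pair", "score_all"]


@dataclass(frozen=True)
class Path:
    """One simple path from an lncRNA endpoint to a disease endpoint."""

    nodes: tuple
    weight_product: float

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.nodes) - 1


@dataclass(frozen=True)
class PairScore:
    lncrna: str
    disease: str
    score: float
    n_paths: int


def _adjacency(net: HeteroNetwork) -> dict:
    """node -> list of (neighbor, weight), a flat view for the DFS hot loop."""
    adj: dict = {n: [] for n in net.graph.nodes}
    for u, v, w in net.graph.edges(data="weight"):
        adj[u].append((v, w))
        adj[v].append((u, w))
    return adj


def enumerate_paths(net: HeteroNetwork, lncrna: str, disease: str,
                    tau: int) -> list[Path]:
    """All simple paths from ``lncrna`` to ``disease`` with 1..tau edges.

    Order of the returned paths is unspecified; each path appears once, always
    oriented from the lncRNA endpoint to the disease endpoint.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    src, dst = lnode(lncrna), dnode(disease)
    for node, label in ((src, lncrna), (dst, disease)):
        if node not in net.graph:
            raise KeyError(f"unknown node {label!r}")
    adj = _adjacency(net)
    paths: list[Path] = []
    stack = [src]
    on_path = {src}

    def dfs(node, depth: int, prod: float) -> None:
        for nbr, w in adj[node]:
            if nbr in on_path:
                continue
            if nbr == dst:
                paths.append(Path(tuple(stack) + (dst,), prod * w))
                continue
            if depth + 1 < tau:
                stack.append(nbr)
                on_path.add(nbr)
                dfs(nbr, depth + 1, prod * w)
                on_path.discard(nbr)
                stack.pop()

    dfs(src, 0, 1.0)
    return paths


def _decay(length: int, prod: float, cfg: NetworkConfig) -> float:
    if cfg.decay_form == "exp_decay":
        return prod * cfg.alpha ** (-length)
    return prod ** (cfg.alpha * length)


def path_score(paths: list[Path], cfg: NetworkConfig) -> float:
    """Sum of decay-weighted path contributions (0 for an empty path set)."""
    return float(sum(_decay(p.length, p.weight_product, cfg) for p in paths))


def score_pair(net: HeteroNetwork, lncrna: str, disease: str,
               cfg: NetworkConfig) -> PairScore:
    """Score one (lncRNA, disease) pair: enumerate paths, then sum decays."""
    paths = enumerate_paths(net, lncrna, disease, cfg.tau)
    return PairScore(lncrna, disease, path_score(paths, cfg), len(paths))


def _scores_from_lncrna(adj: dict, src, cfg: NetworkConfig) -> dict:
    """One DFS from ``src`` accumulating score terms at every disease node."""
    scores: dict = {}
    on_path = {src}

    def dfs(node, depth: int, prod: float) -> None:
        for nbr, w in adj[node]:
            if nbr in on_path:
                continue
            p = prod * w
            if nbr[0] == "D":
                scores[nbr] = scores.get(nbr, 0.0) + _decay(depth + 1, p, cfg)
            if depth + 1 < cfg.tau:
                on_path.add(nbr)
                dfs(nbr, depth + 1, p)
                on_path.discard(nbr)

    dfs(src, 0, 1.0)
    return scores


def score_all(net: HeteroNetwork, data: AssociationDataset,
              cfg: NetworkConfig) -> np.ndarray:
    """Full score matrix (lncRNAs x diseases), entry (i, j) = score of the pair.

    Equivalent to calling :func:`score_pair` for every pair, but runs a single
    depth-limited DFS per lncRNA: every simple path of length <= tau starting
    at l(i) deposits its contribution on the disease node it ends at, so each
    (path, pair) term is counted exactly once.
    """
    adj = _adjacency(net)
    out = np.zeros((data.n_lncrnas, data.n_diseases))
    dindex = {dnode(n): j for j, n in enumerate(data.disease_names)}
    for i, lname in enumerate(data.lncrna_names):
        for node, s in _scores_from_lncrna(adj, lnode(lname), cfg).items():
            out[i, dindex[node]] = s
    return out
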