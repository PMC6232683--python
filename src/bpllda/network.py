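"""Heterogeneous network assembly from LD, DS and LS.

The network has one node per lncRNA and per disease (isolated entities are
kept, so cross-validation over novel entities is well defined) and three edge
classes:

* ``LL`` — lncRNA-lncRNA, weight LS(i, j), kept iff LS(i, j) >= T;
* ``DD`` — disease-disease, weight DS(i, j), kept iff DS(i, j) >= T;
* ``LD`` — association edges of weight exactly 1 wherever LD(i, j) = 1.

The threshold T prunes weak similarity edges so the graph does not become a
near-clique; it never applies to association edges.  Equality is kept (the
pruning rule zeroes weights strictly below T).  Self-loops are never created:
a self-loop cannot appear on a simple path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx

from .core_data import AssociationDataset, SimilarityMatrix

__all__ = ["NetworkConfig", "HeteroNetwork", "lnode", "dnode",
           "build_network", "remove_association", "write_edgelist"]


@dataclass(frozen=True)
class NetworkConfig:
    """Operating point of the predictor.

    T      -- similarity-edge weight threshold in [0, 1] (default 0.2)
    tau    -- maximum number of edges per path, >= 1 (default 3)
    alpha  -- path-length decay factor, > 1 (default 2.26)
    decay_form -- "exp_decay": each path contributes (prod weights) * alpha**(-len);
                  "product_power": contributes (prod weights)**(alpha * len)
    strict_threshold -- use > T instead of >= T for similarity edges
    """

    T: float = 0.2
    tau: int = 3
    alpha: float = 2.26
    decay_form: str = "exp_decay"
    strict_threshold: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.T <= 1.0:
            raise ValueError(f"threshold T must be in [0, 1], got {self.T}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.alpha <= 1.0:
            raise ValueError(f"alpha must be > 1, got {self.alpha}")
        if self.decay_form not in ("exp_decay", "product_power"):
            raise ValueError(f"unknown decay form {self.decay_form!r}")

    def with_(self, **kw) -> "NetworkConfig":
        return replace(self, **kw)


def lnode(name: str) -> tuple[str, str]:
    """Graph node for an lncRNA (class-tagged to avoid name collisions)."""
    return ("L", name)


def dnode(name: str) -> tuple[str, str]:
    """Graph node for a disease."""
    return ("D", name)


@dataclass(frozen=True)
class HeteroNetwork:
    """Weighted undirected graph over lncRNA and disease nodes.

    Backed by a :class:`networkx.Graph`; edges carry ``weight`` in (0, 1] and
    ``kind`` in {"LL", "DD", "LD"}.
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_count(self, kind: str) -> int:
        return sum(1 for *_e, k in self.graph.edges(data="kind") if k == kind)

    def has_association(self, lncrna: str, disease: str) -> bool:
        g = self.graph
        return g.has_edge(lnode(lncrna), dnode(disease))


def build_network(data: AssociationDataset, DS: SimilarityMatrix,
                  LS: SimilarityMatrix, cfg: NetworkConfig) -> HeteroNetwork:
    """Assemble the thresholded heterogeneous network.

    DS/LS must be labelled consistently with ``data`` (they are reindexed to
    its name order, raising on any missing entity).
    """
    DS = DS.reindex(data.disease_names)
    LS = LS.reindex(data.lncrna_names)
    g = nx.Graph()
    g.add_nodes_from((lnode(n) for n in data.lncrna_names), kind="lncrna")
    g.add_nodes_from((dnode(n) for n in data.disease_names), kind="disease")

    def keep(w: float) -> bool:
        return w > cfg.T if cfg.strict_threshold else w >= cfg.T

    ln, dn = data.lncrna_names, data.disease_names
    L = LS.values
    for i in range(len(ln)):
        for j in range(i + 1, len(ln)):
            if L[i, j] > 0.0 and keep(L[i, j]):
                g.add_edge(lnode(ln[i]), lnode(ln[j]), weight=float(L[i, j]), kind="LL")
    Dv = DS.values
    for i in range(len(dn)):
        for j in range(i + 1, len(dn)):
            if Dv[i, j] > 0.0 and keep(Dv[i, j]):
                g.add_edge(dnode(dn[i]), dnode(dn[j]), weight=float(Dv[i, j]), kind="DD")
    for i, j in data.pairs():
        g.add_edge(lnode(ln[i]), dnode(dn[j]), weight=1.0, kind="LD")
    return HeteroNetwork(g)


def remove_association(net: HeteroNetwork, lncrna: str, disease: str) -> HeteroNetwork:
    """Copy of ``net`` without the association edge (lncrna, disease).

    The input network is left unmodified; the edge must exist and be of the
    association class.
    """
    u, v = lnode(lncrna), dnode(disease)
    if not net.graph.has_edge(u, v):
        raise KeyError(f"no association edge between {lncrna!r} and {disease!r}")
    if net.graph.edges[u, v]["kind"] != "LD":
        raise ValueError(f"edge ({lncrna!r}, {disease!r}) is not an association edge")
    g = net.graph.copy()
    g.remove_edge(u, v)
    return HeteroNetwork(g)


def write_edgelist(net: HeteroNetwork, path) -> None:
    """Edge-list TSV (node1, node2, weight, class) for inspection."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# node1\tnode2\tweight\tclass\n")
        for (k1, n1), (k2, n2), d in net.graph.edges(data=True):
            fh.write(f"{k1}:{n1}\t{k2}:{n2}\t{d['weight']:.6g}\t{d['kind']}\n")
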