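"""Leave-one-out cross-validation, ROC/AUC, and parameter-study drivers.

Two protocols:

* **global LOOCV** — every known association is held out once.  The fold
  zeroes that single LD entry, recomputes the whole similarity stage and the
  network from the training matrix (so no information leaks through the
  kernels or FS), and scores the held-out pair.  Negatives are the scores of
  all LD = 0 pairs computed once on the full-data network — their own edges
  are never held out, so nothing changes between folds for them.
* **local LOOCV** — every lncRNA (mode ``novel_lncrna``) or disease
  (``novel_disease``) with at least one association is held out once: its
  entire LD row/column is zeroed, the pipeline recomputed, and the entity
  scored against every entity of the other class.  Its true associations are
  the positives of that fold and its non-associations the negatives.

AUC is the Mann-Whitney statistic — ties get half credit — which equals the
trapezoidal area under the ROC curve produced by sweeping the threshold over
the distinct scores.  ``reuse_similarities=True`` reproduces the cheaper
variant that freezes the full-data similarities and only deletes the held-out
association edge(s) from the network; it is faster but lets the kernels leak.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_data import AssociationDataset, SimilarityMatrix
from .network import HeteroNetwork, NetworkConfig, build_network, dnode, lnode
from .pathscore import score_all, score_pair
from .similarity import KernelParams, compute_similarities

__all__ = ["LoocvResult", "PrecisionBin", "roc_auc", "global_loocv",
           "local_loocv", "precision_bins", "parameter_sweep",
           "kernel_ablation", "DEFAULT_PRECISION_BIN_EDGES"]

#: default score-bin edges for the precision table (four intervals of
#: interest plus the gaps between them)
DEFAULT_PRECISION_BIN_EDGES = (1.002, 9.929, 10.028, 17.601, 21.580, 24.391, 25.778, 37.757)


@dataclass(frozen=True)
class LoocvResult:
    mode: str  # "global" | "novel_lncrna" | "novel_disease"
    positive_scores: tuple[float, ...]
    negative_scores: tuple[float, ...]
    auc: float
    roc_points: tuple[tuple[float, float], ...]
    per_fold: tuple[tuple[str, str, float], ...]


@dataclass(frozen=True)
class PrecisionBin:
    score_lo: float
    score_hi: float
    n_predictions: int
    n_true: int
    precision: float | None  # None when the bin is empty


def roc_auc(positive_scores, negative_scores):
    """(AUC, ROC points) from pooled positive and negative score lists.

    AUC = [#(pos > neg) + 0.5 * #(pos = neg)] / (n_pos * n_neg), computed via
    midranks; the ROC curve sweeps the threshold over the distinct scores
    (ties collapse onto one point), running from (0, 0) to (1, 1).
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)

    points = [(0.0, 0.0)]
    for thr in np.unique(np.concatenate([pos, neg]))[::-1]:
        points.append((float((neg >= thr).mean()), float((pos >= thr).mean())))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return float(auc), tuple(points)


def _fold_network(data, LD_train, SS, cfg, params, use_gl=True, use_gd=True,
                  use_kernels=True, agg="max"):
    """Similarity stage + network from a training adjacency matrix."""
    train = data.with_LD(LD_train)
    if use_kernels:
        DS, LS = compute_similarities(train, SS, params, use_gl=use_gl,
                                      use_gd=use_gd, agg=agg)
    else:
        DS = SS.reindex(data.disease_names)
        from .similarity import functional_similarity
        LS = functional_similarity(train, SS, agg=agg)
    return build_network(train, DS, LS, cfg)


def global_loocv(
    data: AssociationDataset,
    SS: SimilarityMatrix,
    cfg: NetworkConfig = NetworkConfig(),
    params: KernelParams = KernelParams(),
    reuse_similarities: bool = False,
    use_gl: bool = True,
    use_gd: bool = True,
    use_kernels: bool = True,
    agg: str = "max",
) -> LoocvResult:
    """Hold out each known association once and score it without its edge."""
    if data.n_associations < 2:
        raise ValueError("global LOOCV needs at least two associations")
    SS = SS.reindex(data.disease_names)
    kw = dict(use_gl=use_gl, use_gd=use_gd, use_kernels=use_kernels, agg=agg)

    full_net = _fold_network(data, data.LD, SS, cfg, params, **kw)
    neg_matrix = score_all(full_net, data, cfg)
    negatives = tuple(float(s) for s in neg_matrix[data.LD == 0])

    positives = []
    per_fold = []
    for i, j in data.pairs():
        lname, dname = data.lncrna_names[i], data.disease_names[j]
        if reuse_similarities:
            from .network import remove_association
            net = remove_association(full_net, lname, dname)
        else:
            LD_train = data.LD.copy()
            LD_train[i, j] = 0.0
            net = _fold_network(data, LD_train, SS, cfg, params, **kw)
        assert not net.has_association(lname, dname), "held-out edge leaked into fold network"
        s = score_pair(net, lname, dname, cfg).score
        positives.append(s)
        per_fold.append((lname, dname, s))

    auc, points = roc_auc(positives, negatives)
    return LoocvResult("global", tuple(positives), negatives, auc, points,
                       tuple(per_fold))


def local_loocv(
    data: AssociationDataset,
    SS: SimilarityMatrix,
    cfg: NetworkConfig = NetworkConfig(),
    params: KernelParams = KernelParams(),
    mode: str = "novel_lncrna",
    reuse_similarities: bool = False,
    agg: str = "max",
) -> LoocvResult:
    """Hold out all associations of one entity at a time (novel-entity test).

    For every lncRNA (or disease) with at least one association, its entire LD
    row (column) is zeroed, the pipeline rebuilt, and the entity scored
    against every entity of the other class; scores pool over folds.
    """
    if mode not in ("novel_lncrna", "novel_disease"):
        raise ValueError(f"unknown mode {mode!r}")
    SS = SS.reindex(data.disease_names)
    by_lncrna = mode == "novel_lncrna"
    n_entities = data.n_lncrnas if by_lncrna else data.n_diseases

    positives, negatives, per_fold = [], [], []
    full_net = (_fold_network(data, data.LD, SS, cfg, params, agg=agg)
                if reuse_similarities else None)
    for e in range(n_entities):
        truth = data.LD[e, :] if by_lncrna else data.LD[:, e]
        if truth.sum() == 0:
            continue
        LD_train = data.LD.copy()
        if by_lncrna:
            LD_train[e, :] = 0.0
        else:
            LD_train[:, e] = 0.0
        if reuse_similarities:
            net = _strip_entity_edges(full_net, data, e, by_lncrna)
        else:
            net = _fold_network(data, LD_train, SS, cfg, params, agg=agg)
        scores = score_all(net, data, cfg)
        fold_scores = scores[e, :] if by_lncrna else scores[:, e]
        ename = data.lncrna_names[e] if by_lncrna else data.disease_names[e]
        others = data.disease_names if by_lncrna else data.lncrna_names
        for k, s in enumerate(fold_scores):
            (positives if truth[k] else negatives).append(float(s))
            pair = (ename, others[k]) if by_lncrna else (others[k], ename)
            per_fold.append((*pair, float(s)))

    auc, points = roc_auc(positives, negatives)
    return LoocvResult(mode, tuple(positives), tuple(negatives), auc, points,
                       tuple(per_fold))


def _strip_entity_edges(net, data, e, by_lncrna):
    node = lnode(data.lncrna_names[e]) if by_lncrna else dnode(data.disease_names[e])
    g = net.graph.copy()
    g.remove_edges_from([(u, v) for u, v, k in g.edges(node, data="kind") if k == "LD"])
    return HeteroNetwork(g)


def precision_bins(result: LoocvResult, bin_edges=DEFAULT_PRECISION_BIN_EDGES) -> list[PrecisionBin]:
    """Precision of held-out predictions per score interval.

    Bins are consecutive [lo, hi) intervals over the given strictly increasing
    edges (the last bin closes at its upper edge).  Precision in a bin is the
    fraction of scored pairs falling in it that are true associations; empty
    bins report precision ``None``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not (np.diff(edges) > 0).all():
        raise ValueError("bin edges must be strictly increasing")
    scores = np.concatenate([result.positive_scores, result.negative_scores])
    labels = np.concatenate([np.ones(len(result.positive_scores)),
                             np.zeros(len(result.negative_scores))])
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        mask = (scores >= lo) & ((scores <= hi) if last else (scores < hi))
        n = int(mask.sum())
        t = int(labels[mask].sum())
        out.append(PrecisionBin(float(lo), float(hi), n, t,
                                t / n if n else None))
    return out


def parameter_sweep(
    data: AssociationDataset,
    SS: SimilarityMatrix,
    T_values,
    L_values,
    cfg: NetworkConfig = NetworkConfig(),
    params: KernelParams = KernelParams(),
    time_budget: float | None = None,
    **loocv_kw,
) -> pd.DataFrame:
    """Global LOOCV AUC over a (T, L) grid; rows T, columns L.

    ``time_budget`` (seconds, optional) bounds the whole sweep: cells starting
    after the budget is spent are left NaN and reported as skipped.
    """
    table = pd.DataFrame(index=list(T_values), columns=list(L_values), dtype=float)
    table.index.name = "T"
    table.columns.name = "L"
    start = time.monotonic()
    for T in T_values:
        for L in L_values:
            if time_budget is not None and time.monotonic() - start > time_budget:
                continue  # skipped cell stays NaN
            res = global_loocv(data, SS, cfg.with_(T=T, tau=int(L)), params,
                               **loocv_kw)
            table.loc[T, L] = res.auc
    return table


def kernel_ablation(
    data: AssociationDataset,
    SS: SimilarityMatrix,
    cfg: NetworkConfig = NetworkConfig(),
    params: KernelParams = KernelParams(),
    **loocv_kw,
) -> dict[str, float]:
    """Global LOOCV AUC under the four kernel-integration settings.

    "none" uses DS = SS and LS = FS with no fallback substitution; "gl" and
    "gd" enable one kernel each; "both" is the full model.
    """
    settings = {
        "none": dict(use_kernels=False),
        "gl": dict(use_gl=True, use_gd=False),
        "gd": dict(use_gl=False, use_gd=True),
        "both": dict(use_gl=True, use_gd=True),
    }
    return {name: global_loocv(data, SS, cfg, params, **kw, **loocv_kw).auc
            for name, kw in settings.items()}
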