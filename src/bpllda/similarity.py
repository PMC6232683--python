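"""Similarity computation: functional, Gaussian-kernel, and integrated.

Four similarity layers feed the heterogeneous network:

* **FS** — lncRNA functional similarity, derived from the disease semantic
  similarity SS by best-match aggregation over each lncRNA's associated
  disease set.
* **GL / GD** — Gaussian interaction-profile kernels over LD rows / columns,
  ``exp(-gamma * ||IP_i - IP_j||^2)`` with the bandwidth normalized by the
  mean squared profile norm (gamma' defaults to 1).
* **DS / LS** — the integrated similarities: SS (resp. FS) with the kernel
  substituted for every entity that has no semantic (resp. functional)
  similarity to any other entity — the fallback sets NS and NF.

FS uses the best-match convention: the similarity between one disease d and
a disease group D is ``max_{d' in D} SS(d, d')``, and FS(i, j) averages these
best matches in both directions over m + n terms.  A mean aggregation is
available behind ``agg="mean"`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .core_data import AssociationDataset, SimilarityMatrix

__all__ = [
    "KernelParams",
    "FallbackSets",
    "group_similarity",
    "functional_similarity",
    "gaussian_kernel",
    "lncrna_kernel",
    "disease_kernel",
    "fallback_sets",
    "integrate",
    "compute_similarities",
]


@dataclass(frozen=True)
class KernelParams:
    """Bandwidth regulation for the interaction-profile kernels.

    The effective bandwidth is gamma = gamma' / mean(||IP||^2) over all
    entities of the class, so gamma' = 1 (the customary choice) makes the
    kernel scale-free in the overall association density.
    """

    gamma_prime_l: float = 1.0
    gamma_prime_d: float = 1.0


@dataclass(frozen=True)
class FallbackSets:
    """Entities whose similarity row is all-zero off the diagonal.

    NS: disease indices with no semantic similarity to any other disease;
    NF: lncRNA indices with no functional similarity to any other lncRNA.
    The integrated similarities replace these rows/columns with the kernel.
    """

    NS: frozenset[int]
    NF: frozenset[int]


def group_similarity(d: int, D: "set[int] | np.ndarray | list[int]",
                     SS: SimilarityMatrix, agg: str = "max") -> float:
    """Similarity between disease ``d`` and a non-empty disease group ``D``."""
    idx = np.asarray(sorted(D) if isinstance(D, set) else D, dtype=int)
    if idx.size == 0:
        raise ValueError("disease group must be non-empty")
    row = SS.values[d, idx]
    return float(row.max() if agg == "max" else row.mean())


def functional_similarity(data: AssociationDataset, SS: SimilarityMatrix,
                          agg: str = "max") -> SimilarityMatrix:
    """lncRNA functional similarity FS from SS and the association sets.

    FS(i, j) = [sum_k SIM(d_ik, D_j) + sum_l SIM(d_jl, D_i)] / (m + n) where
    D_i (size m) and D_j (size n) are the associated-disease sets, and SIM is
    the group best-match (or mean, per ``agg``).  lncRNAs with an empty
    disease set — possible inside cross-validation folds — get off-diagonal 0
    and diagonal 1, which sweeps them into the kernel fallback set NF.
    """
    if agg not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {agg!r}")
    SS = SS.reindex(data.disease_names)
    S = SS.values
    dsets = data.disease_sets()
    n = data.n_lncrnas
    FS = np.zeros((n, n))
    for i in range(n):
        Di = dsets[i]
        FS[i, i] = 1.0
        if Di.size == 0:
            continue
        for j in range(i + 1, n):
            Dj = dsets[j]
            if Dj.size == 0:
                continue
            block = S[np.ix_(Di, Dj)]
            if agg == "max":
                total = block.max(axis=1).sum() + block.max(axis=0).sum()
            else:
                total = block.mean(axis=1).sum() + block.mean(axis=0).sum()
            FS[i, j] = FS[j, i] = total / (Di.size + Dj.size)
    return SimilarityMatrix(data.lncrna_names, np.clip(FS, 0.0, 1.0))


def gaussian_kernel(profiles: np.ndarray, gamma_prime: float = 1.0,
                    names: tuple[str, ...] | None = None) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary profile vectors.

    K(i, j) = exp(-gamma * ||IP_i - IP_j||^2), gamma = gamma_prime divided by
    the mean squared profile norm over *all* profiles (zero rows included).
    The diagonal is exactly 1 and all entries are strictly positive.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2:
        raise ValueError("profiles must be a 2-D array (entities x features)")
    mean_sq = float((P * P).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError("bandwidth undefined: all interaction profiles are zero")
    gamma = gamma_prime / mean_sq
    sq = squareform(pdist(P, metric="sqeuclidean")) if len(P) > 1 else np.zeros((1, 1))
    K = np.exp(-gamma * sq)
    np.fill_diagonal(K, 1.0)
    K = np.triu(K, 1)
    K = K + K.T + np.eye(len(P))  # exact symmetry
    if names is None:
        names = tuple(f"p{i}" for i in range(len(P)))
    return SimilarityMatrix(names, K)


def lncrna_kernel(data: AssociationDataset, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """GL: kernel over LD rows (lncRNA interaction profiles)."""
    return gaussian_kernel(data.LD, gamma_prime, data.lncrna_names)


def disease_kernel(data: AssociationDataset, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """GD: kernel over LD columns (disease interaction profiles)."""
    return gaussian_kernel(data.LD.T, gamma_prime, data.disease_names)


def fallback_sets(SS: SimilarityMatrix, FS: SimilarityMatrix) -> FallbackSets:
    """Compute NS (from SS) and NF (from FS) from off-diagonal zeros."""
    return FallbackSets(NS=_all_zero_rows(SS), NF=_all_zero_rows(FS))


def _all_zero_rows(sim: SimilarityMatrix) -> frozenset[int]:
    v = sim.values.copy()
    np.fill_diagonal(v, 0.0)
    return frozenset(np.flatnonzero((v == 0.0).all(axis=1)).tolist())


def integrate(primary: SimilarityMatrix, kernel: SimilarityMatrix,
              fallback: "frozenset[int] | set[int]") -> SimilarityMatrix:
    """Integrated similarity: kernel where either index is in the fallback set.

    Entry (i, j) is kernel(i, j) if i or j lacks primary similarity to every
    other entity, and primary(i, j) otherwise.  Symmetric by construction.
    """
    if primary.names != kernel.names:
        raise ValueError("primary and kernel must be indexed over the same names")
    out = primary.values.copy()
    idx = sorted(fallback)
    if idx:
        out[idx, :] = kernel.values[idx, :]
        out[:, idx] = kernel.values[:, idx]
    return SimilarityMatrix(primary.names, out)


def compute_similarities(
    data: AssociationDataset,
    SS: SimilarityMatrix,
    params: KernelParams = KernelParams(),
    use_gl: bool = True,
    use_gd: bool = True,
    agg: str = "max",
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Full similarity stage: (DS, LS) from the association data and SS.

    ``use_gl`` / ``use_gd`` switch the kernel fallback off for ablation
    studies; with both off, DS is SS and LS is FS unchanged.
    """
    SS = SS.reindex(data.disease_names)
    FS = functional_similarity(data, SS, agg=agg)
    fb = fallback_sets(SS, FS)
    LS = integrate(FS, lncrna_kernel(data, params.gamma_prime_l), fb.NF) if use_gl else FS
    DS = integrate(SS, disease_kernel(data, params.gamma_prime_d), fb.NS) if use_gd else SS
    return DS, LS
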