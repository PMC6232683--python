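"""Domain containers and text I/O for association tables and similarity matrices.

The central objects are :class:`AssociationDataset` — the binary lncRNA x
disease adjacency matrix ``LD`` together with its ordered name lists — and
:class:`SimilarityMatrix`, a labelled symmetric square matrix with entries in
[0, 1] that serves every similarity role in the pipeline (disease semantic
similarity SS, lncRNA functional similarity FS, the Gaussian interaction
profile kernels GL/GD, and the integrated similarities DS/LS).

File formats are deliberately plain: associations are a two-column
tab-separated list (lncRNA name, disease name; ``#`` comments ignored), and
similarity matrices are labelled TSV tables readable by any spreadsheet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssociationDataset",
    "SimilarityMatrix",
    "DatasetStats",
    "normalize_name",
    "read_associations",
    "write_associations",
    "read_similarity",
    "write_similarity",
    "dataset_stats",
    "format_stats",
    "zero_fraction",
]

#: tolerance for symmetry / range validation of similarity matrices
SYMMETRY_TOL = 1e-9


def normalize_name(name: str) -> str:
    """Canonical matching key for free-text entity names.

    Trims surrounding whitespace, collapses internal whitespace runs to a
    single space, and case-folds.  The first-seen original spelling is kept
    for output; this key is only used for identity.
    """
    return " ".join(name.split()).casefold()


@dataclass(frozen=True)
class AssociationDataset:
    """Known lncRNA-disease associations as a binary adjacency matrix.

    ``LD[i, j] == 1`` iff lncRNA ``lncrna_names[i]`` is associated with
    disease ``disease_names[j]``.  Rows of ``LD`` are the lncRNA interaction
    profiles IP(l(i)); columns are the disease interaction profiles IP(d(j)).
    """

    lncrna_names: tuple[str, ...]
    disease_names: tuple[str, ...]
    LD: np.ndarray

    def __post_init__(self) -> None:
        LD = np.asarray(self.LD, dtype=float)
        if LD.shape != (len(self.lncrna_names), len(self.disease_names)):
            raise ValueError(
                f"LD shape {LD.shape} does not match "
                f"({len(self.lncrna_names)}, {len(self.disease_names)}) names"
            )
        if not np.isin(LD, (0.0, 1.0)).all():
            raise ValueError("LD must be binary")
        for label, names in (("lncRNA", self.lncrna_names), ("disease", self.disease_names)):
            keys = [normalize_name(n) for n in names]
            if len(set(keys)) != len(keys):
                raise ValueError(f"duplicate {label} names after normalization")
        object.__setattr__(self, "LD", LD)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrna_names)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_names)

    @property
    def n_associations(self) -> int:
        return int(self.LD.sum())

    def lncrna_index(self, name: str) -> int:
        return self._lidx()[normalize_name(name)]

    def disease_index(self, name: str) -> int:
        return self._didx()[normalize_name(name)]

    def _lidx(self) -> dict[str, int]:
        return {normalize_name(n): i for i, n in enumerate(self.lncrna_names)}

    def _didx(self) -> dict[str, int]:
        return {normalize_name(n): j for j, n in enumerate(self.disease_names)}

    def disease_sets(self) -> list[np.ndarray]:
        """Per-lncRNA arrays of associated disease indices (the sets D_i)."""
        return [np.flatnonzero(row) for row in self.LD]

    def pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i, j) of all known associations."""
        return list(zip(*np.nonzero(self.LD)))

    def with_LD(self, LD: np.ndarray) -> "AssociationDataset":
        """Same entities, different adjacency (used for cross-validation folds)."""
        return AssociationDataset(self.lncrna_names, self.disease_names, LD)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Labelled symmetric square matrix with entries in [0, 1]."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} does not match {n} names")
        if not np.array_equal(v, v.T):
            raise ValueError("similarity matrix must be exactly symmetric")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("similarity values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        key = normalize_name(name)
        for i, n in enumerate(self.names):
            if normalize_name(n) == key:
                return i
        raise KeyError(name)

    def reindex(self, names: Sequence[str]) -> "SimilarityMatrix":
        """Restrict/reorder to ``names``; raises naming any missing entity."""
        lookup = {normalize_name(n): i for i, n in enumerate(self.names)}
        idx = []
        for name in names:
            key = normalize_name(name)
            if key not in lookup:
                raise KeyError(f"similarity matrix has no entry for {name!r}")
            idx.append(lookup[key])
        idx = np.asarray(idx)
        return SimilarityMatrix(tuple(names), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class DatasetStats:
    """Summary characteristics of an association dataset.

    Degrees are LD row/column sums; averages are reported rounded to one
    decimal place, matching the conventional presentation of such tables.
    """

    n_lncrnas: int
    n_diseases: int
    n_associations: int
    avg_deg_lncrna: float
    avg_deg_disease: float
    max_deg_lncrna: int
    max_deg_disease: int
    min_deg: int

    def as_tuple(self) -> tuple:
        return (
            self.n_lncrnas,
            self.n_diseases,
            self.n_associations,
            self.avg_deg_lncrna,
            self.avg_deg_disease,
            self.max_deg_lncrna,
            self.max_deg_disease,
            self.min_deg,
        )


class ParseError(ValueError):
    """Raised for malformed input files, naming the offending line."""


# -- association tables -------------------------------------------------------


def read_associations(path: str | Path) -> AssociationDataset:
    """Load a two-column tab-separated association list.

    Duplicate (lncRNA, disease) pairs collapse to a single association; entity
    order is first-appearance order; names match after whitespace/case
    normalization but keep their first-seen spelling.
    """
    path = Path(path)
    lncrnas: dict[str, str] = {}  # norm key -> original spelling
    diseases: dict[str, str] = {}
    pairs: set[tuple[str, str]] = set()
    n_lines = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}:{lineno}: expected two tab-separated fields "
                    f"(lncRNA, disease), got {line!r}"
                )
            n_lines += 1
            lk, dk = normalize_name(fields[0]), normalize_name(fields[1])
            lncrnas.setdefault(lk, " ".join(fields[0].split()))
            diseases.setdefault(dk, " ".join(fields[1].split()))
            pairs.add((lk, dk))
    if not pairs:
        raise ParseError(f"{path}: no associations found")
    lnames = tuple(lncrnas.values())
    dnames = tuple(diseases.values())
    lidx = {k: i for i, k in enumerate(lncrnas)}
    didx = {k: j for j, k in enumerate(diseases)}
    LD = np.zeros((len(lnames), len(dnames)))
    for lk, dk in pairs:
        LD[lidx[lk], didx[dk]] = 1.0
    return AssociationDataset(lnames, dnames, LD)


def write_associations(data: AssociationDataset, path: str | Path) -> None:
    """Write the association list as two-column TSV (one line per pair)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# lncRNA\tdisease\n")
        for i, j in data.pairs():
            fh.write(f"{data.lncrna_names[i]}\t{data.disease_names[j]}\n")


# -- labelled similarity matrices ---------------------------------------------


def read_similarity(path: str | Path) -> SimilarityMatrix:
    """Load a labelled square similarity matrix from TSV.

    Row and column labels must agree (after name normalization).  Symmetry is
    enforced to within 1e-9 and then made exact by averaging; values straying
    outside [0, 1] by at most 1e-9 are clipped, anything worse is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    row_keys = [normalize_name(str(n)) for n in df.index]
    col_keys = [normalize_name(str(n)) for n in df.columns]
    if row_keys != col_keys:
        raise ParseError(f"{path}: row and column labels differ")
    if len(set(row_keys)) != len(row_keys):
        raise ParseError(f"{path}: duplicate labels")
    v = df.to_numpy(dtype=float)
    asym = np.abs(v - v.T).max() if v.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ParseError(f"{path}: matrix asymmetric by {asym:.3g} (> {SYMMETRY_TOL})")
    v = (v + v.T) / 2.0
    if v.min() < -SYMMETRY_TOL or v.max() > 1.0 + SYMMETRY_TOL:
        raise ParseError(f"{path}: values outside [0, 1]")
    v = np.clip(v, 0.0, 1.0)
    return SimilarityMatrix(tuple(str(n) for n in df.index), v)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.values, index=list(sim.names), columns=list(sim.names))
    df.to_csv(path, sep="\t")


# -- summary statistics -------------------------------------------------------


def dataset_stats(data: AssociationDataset) -> DatasetStats:
    """Degree-based summary of an association dataset."""
    row_deg = data.LD.sum(axis=1)
    col_deg = data.LD.sum(axis=0)
    n_assoc = int(data.LD.sum())
    if n_assoc == 0:
        warnings.warn("empty dataset: all statistics are zero", stacklevel=2)
        return DatasetStats(data.n_lncrnas, data.n_diseases, 0, 0.0, 0.0, 0, 0, 0)
    return DatasetStats(
        n_lncrnas=data.n_lncrnas,
        n_diseases=data.n_diseases,
        n_associations=n_assoc,
        avg_deg_lncrna=round(n_assoc / data.n_lncrnas, 1),
        avg_deg_disease=round(n_assoc / data.n_diseases, 1),
        max_deg_lncrna=int(row_deg.max()),
        max_deg_disease=int(col_deg.max()),
        min_deg=int(min(row_deg.min(), col_deg.min())),
    )


def format_stats(stats: DatasetStats) -> str:
    """Render statistics as key=value lines."""
    return "\n".join(f"{k}={v}" for k, v in vars(stats).items())


def zero_fraction(sim: SimilarityMatrix) -> float:
    """Fraction of exactly-zero entries over all n**2 entries (diagonal included)."""
    if sim.values.size == 0:
        return 0.0
    return float(np.count_nonzero(sim.values == 0.0) / sim.values.size)
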