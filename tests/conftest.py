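import numpy as np
import pytest

from bpllda import (
    AssociationDataset,
    NetworkConfig,
    SimilarityMatrix,
    build_network,
)


@pytest.fixture
def write_assoc(tmp_path):
    """Factory writing an association TSV from a list of (lncrna, disease) lines."""

    def _write(pairs, name="assoc.tsv"):
        path = tmp_path / name
        path.write_text("".join(f"{l}\t{d}\n" for l, d in pairs), encoding="utf-8")
        return path

    return _write


@pytest.fixture
def three_edge_net():
    """The worked fixture: l1-d1 (1), l2-d1 (1), l1-l2 (0.5); T=0.2, tau=3.

    Scoring (l1, d1) gives two paths, [l1, d1] and [l1, l2, d1], hence
    score = 1/alpha + 0.5/alpha**2 under the default decay.
    """
    data = AssociationDataset(("l1", "l2"), ("d1",), np.array([[1.0], [1.0]]))
    LS = SimilarityMatrix(("l1", "l2"), np.array([[1.0, 0.5], [0.5, 1.0]]))
    DS = SimilarityMatrix(("d1",), np.array([[1.0]]))
    cfg = NetworkConfig()
    return build_network(data, DS, LS, cfg), data, cfg


def random_instance(rng, max_l=8, max_d=8):
    """Random small association dataset + strictly valid SS matrix."""
    nl = rng.integers(2, max_l + 1)
    nd = rng.integers(2, max_d + 1)
    LD = (rng.random((nl, nd)) < 0.4).astype(float)
    for i in range(nl):  # keep every lncRNA attached
        if LD[i].sum() == 0:
            LD[i, rng.integers(nd)] = 1.0
    data = AssociationDataset(
        tuple(f"l{i}" for i in range(nl)),
        tuple(f"d{j}" for j in range(nd)),
        LD,
    )
    S = rng.random((nd, nd)) * (rng.random((nd, nd)) < 0.6)
    S = np.triu(S, 1)
    S = S + S.T
    np.fill_diagonal(S, 1.0)
    SS = SimilarityMatrix(data.disease_names, S)
    return data, SS
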