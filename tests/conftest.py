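import numpy as np
import pytest

from corrank import ExpressionMatrix, GroupLabels


def make_em(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    G, M = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(G)]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(M)]
    return ExpressionMatrix(values, gene_ids, sample_ids)


def rand_em(G, M, seed=0) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    return make_em(rng.standard_normal((G, M)))


def split_labels(M1, M2, sample_ids=None) -> GroupLabels:
    """First M1 samples -> group 1, next M2 -> group 2."""
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(M1 + M2)]
    return GroupLabels.from_arrays(sample_ids, [1] * M1 + [2] * M2)


@pytest.fixture
def tiny_X():
    """Two genes over 4 samples; gene g0 is the worked 3/sqrt(2) example."""
    return make_em([[0.0, 2.0, 3.0, 5.0], [1.0, 0.0, 2.0, 4.0]])


@pytest.fixture
def tiny_labels():
    return split_labels(2, 2)
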