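import numpy as np
import pytest

from synprop import BiomarkerLabels, ExpressionMatrix, PPINetwork


def make_expression(values) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    d, n = values.shape
    return ExpressionMatrix(
        values=values,
        protein_ids=[f"P{i}" for i in range(d)],
        sample_ids=[f"S{j}" for j in range(n)],
    )


def make_network(weights) -> PPINetwork:
    W = np.asarray(weights, dtype=float)
    return PPINetwork(weights=W, protein_ids=[f"P{i}" for i in range(W.shape[0])])


def random_network(d: int, p: float, rng: np.random.Generator) -> PPINetwork:
    W = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            if rng.uniform() < p:
                W[i, j] = W[j, i] = rng.uniform(0.05, 1.0)
    return make_network(W)


def make_labels(label_dict, n) -> BiomarkerLabels:
    return BiomarkerLabels(
        labels={b: np.asarray(v) for b, v in label_dict.items()},
        sample_ids=[f"S{j}" for j in range(n)],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
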