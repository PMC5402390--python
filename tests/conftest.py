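import numpy as np
import pandas as pd
import pytest

from rocnet import SyntheticSpec, TwoGroupSample, empirical_roc, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_sample():
    """Three-vs-three sample with one cross-group tie; AUC = 7/9."""
    return TwoGroupSample("toy", [2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


@pytest.fixture
def diagonal_curve():
    return empirical_roc(TwoGroupSample("diag", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))


@pytest.fixture
def perfect_curve():
    return empirical_roc(TwoGroupSample("perfect", [10.0, 20.0], [1.0, 2.0]))


@pytest.fixture
def small_dataset():
    """k=4 factors, two shifted, n=m=60, deterministic."""
    spec = SyntheticSpec(k=4, n=60, m=60, shifts=(1.5, 1.0, 0.0, 0.0), seed=5)
    return generate(spec)


def pairwise_auc(diseased, healthy):
    """O(nm) Mann-Whitney oracle: mean of 1(u > v) + 0.5 * 1(u = v)."""
    u = np.asarray(diseased)[:, None]
    v = np.asarray(healthy)[None, :]
    return float(np.mean((u > v) + 0.5 * (u == v)))
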