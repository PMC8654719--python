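import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from esbench import (
    SyntheticConfig,
    clean_effects,
    generate_effect_dataset,
    generate_meta_dataset,
    harmonize_all,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic literature (760 raw rows, seed 11)."""
    return generate_effect_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def harmonized_records(default_dataset):
    records, _ = default_dataset
    return harmonize_all(clean_effects(records).retained)


@pytest.fixture(scope="session")
def meta_dataset():
    return generate_meta_dataset(SyntheticConfig(seed=11))


def brute_force_sandwich(y, x, groups):
    """Independent oracle: cluster sandwich with the Stata small-sample factor.

    Scores are summed within clusters, the meat is the sum of score outer
    products, and the variance is scaled by [G/(G-1)]*[(N-1)/(N-k)]; returns
    (intercept, slope) and the slope standard error.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    groups = np.asarray(groups)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    meat = np.zeros((2, 2))
    for g in np.unique(groups):
        s = X[groups == g].T @ resid[groups == g]
        meat += np.outer(s, s)
    G = len(np.unique(groups))
    N, k = len(y), 2
    c = (G / (G - 1)) * ((N - 1) / (N - k))
    bread = np.linalg.inv(X.T @ X)
    V = c * bread @ meat @ bread
    return beta, float(np.sqrt(V[1, 1]))
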