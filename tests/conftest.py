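import numpy as np
import pytest

import robustridge as rr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(rng, n=30, p=4, rho=0.0, sigma=1.0, beta=None):
    """Random standardized dataset with optional collinearity."""
    if rho > 0:
        X_raw = rr.generate_design(n, p, rho, rng) * 3.0 + rng.normal(size=p)
    else:
        X_raw = rng.normal(size=(n, p))
    if beta is None:
        beta = rng.normal(size=p)
    y_raw = X_raw @ beta + sigma * rng.standard_normal(n) + 2.0
    return rr.standardize_design(X_raw, y_raw)


def make_setting(rng, p=4, k=None, d=None):
    """Random theoretical MSE setting with positive eigenvalues."""
    return rr.TheoreticalSetting(
        lambdas=rng.uniform(0.05, 5.0, size=p),
        alpha=rng.normal(0, 2, size=p),
        sigma2=float(rng.uniform(0.1, 4.0)),
        omega_diag=rng.uniform(0.01, 5.0, size=p),
        k=float(rng.uniform(0.01, 5.0)) if k is None else k,
        d=float(rng.uniform(0.0, 1.0)) if d is None else d,
    )


@pytest.fixture
def dataset(rng):
    return make_dataset(rng)
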