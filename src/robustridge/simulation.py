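"""Monte Carlo engine for comparing the estimator family.

A scenario draws a correlated design once, sets the true coefficient
vector to the leading unit eigenvector of X'X (so beta'beta = 1), then
repeatedly simulates Gaussian responses, optionally corrupts one or two
observations in the y-direction, fits every estimator at every (k, d)
grid cell, and aggregates the empirical scalar MSE

    mse(alpha_hat) = (1/reps) sum_j (alpha_hat_j - alpha)'(alpha_hat_j - alpha)

together with its Monte Carlo standard error.

Design columns are correlated via x_ij = sqrt(1 - rho^2) z_ij + rho z_i,p+1
with iid standard-normal z, giving every pair of raw columns population
correlation rho^2.  Per-replication random streams are derived from
numpy SeedSequence(seed, rep) so results are reproducible and
independent of execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CanonicalForm,
    Estimator,
    HuberConfig,
    _standardize_columns,
    apply_shrinkage,
    fit_huber_m,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "generate_design",
    "true_coefficients",
    "simulate_response",
    "inject_outliers",
    "estimate_empirical_mse",
    "run_scenario",
    "run_grid",
]

_ALL_ESTIMATORS = (Estimator.OLS, Estimator.M, Estimator.RIDGE,
                   Estimator.RIDGE_M, Estimator.MRT, Estimator.RTMME)


@dataclass
class ScenarioSpec:
    """One cell of the factorial simulation design."""

    n: int = 20
    p: int = 3
    rho: float = 0.9
    sigma: float = 1.0
    n_outliers: int = 0
    k_grid: tuple = (0.3, 0.7, 0.9)
    d_grid: tuple = (0.2, 0.5, 0.8)
    reps: int = 2000
    seed: int = 0
    redraw_design: bool = False

    def __post_init__(self) -> None:
        if not self.n > self.p + 1:
            raise ValueError("require n > p + 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_outliers not in (0, 1, 2):
            raise ValueError("n_outliers must be 0, 1 or 2")
        if self.n_outliers > 0 and self.n < 10:
            raise ValueError("outlier scheme needs n >= 10")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.k_grid or not self.d_grid:
            raise ValueError("grids must be non-empty")


@dataclass
class ScenarioResult:
    """Estimated-MSE table of one scenario, keyed by (estimator, k, d)."""

    spec: ScenarioSpec
    mse_table: dict
    mc_se: dict
    true_alpha: np.ndarray
    nonconverged: int = 0


def generate_design(n: int, p: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Correlated design, centered and scaled to unit column norm."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    z = rng.standard_normal((n, p + 1))
    X_raw = np.sqrt(1.0 - rho**2) * z[:, :p] + rho * z[:, [p]]
    X, _, _ = _standardize_columns(X_raw)
    return X


def true_coefficients(X: np.ndarray) -> np.ndarray:
    """Unit-norm eigenvector of X'X for the largest eigenvalue.

    Sign convention: first entry of magnitude above tolerance positive.
    A tie in the leading eigenvalue keeps the stable-sorted first vector
    and warns.
    """
    XtX = X.T @ X
    evals, evecs = np.linalg.eigh(XtX)
    order = np.argsort(evals, kind="stable")[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals.shape[0] > 1 and np.isclose(evals[0], evals[1], rtol=1e-10):
        warnings.warn("tied largest eigenvalue; using stable-sorted first")
    beta = evecs[:, 0]
    nz = np.nonzero(np.abs(beta) > 1e-12)[0]
    if nz.size and beta[nz[0]] < 0:
        beta = -beta
    return beta / np.linalg.norm(beta)


def simulate_response(X: np.ndarray, beta: np.ndarray, sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian responses y = X beta + eps, eps ~ N(0, sigma^2); zero intercept."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return X @ beta + sigma * rng.standard_normal(X.shape[0])


def inject_outliers(y: np.ndarray, n_outliers: int, sigma: float) -> np.ndarray:
    """Shift observation 10 by +20 sigma (one outlier) or observations 5
    and 10 by +/-20 sigma (two outliers); positions are 1-based."""
    if n_outliers == 0:
        return y
    if n_outliers not in (1, 2):
        raise ValueError("n_outliers must be 0, 1 or 2")
    if y.shape[0] < 10:
        raise ValueError("outlier scheme needs n >= 10")
    out = y.copy()
    if n_outliers == 1:
        out[9] += 20.0 * sigma
    else:
        out[4] += 20.0 * sigma
        out[9] -= 20.0 * sigma
    return out


def estimate_empirical_mse(alpha_hats: np.ndarray,
                           true_alpha: np.ndarray) -> tuple[float, float]:
    """Empirical scalar MSE over replications plus its Monte Carlo SE."""
    alpha_hats = np.atleast_2d(np.asarray(alpha_hats, dtype=float))
    err = alpha_hats - np.asarray(true_alpha, dtype=float)
    sq = np.sum(err**2, axis=1)
    reps = sq.shape[0]
    mse = float(np.mean(sq))
    se = float(np.std(sq, ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return mse, se


def _canonical_from_design(X: np.ndarray):
    """Eigendecomposition of X'X with the package sign convention."""
    evals, evecs = np.linalg.eigh(X.T @ X)
    order = np.argsort(evals, kind="stable")[::-1]
    lambdas, T = evals[order], evecs[:, order]
    for j in range(T.shape[1]):
        nz = np.nonzero(np.abs(T[:, j]) > 1e-12)[0]
        if nz.size and T[nz[0], j] < 0:
            T[:, j] = -T[:, j]
    return lambdas, T, X @ T


def run_scenario(spec: ScenarioSpec, config: HuberConfig | None = None,
                 estimators: tuple = _ALL_ESTIMATORS) -> ScenarioResult:
    """Run one scenario and aggregate the per-cell empirical MSEs.

    The design is drawn once per scenario by default (redraw_design
    regenerates it every replication).  OLS and M do not depend on
    (k, d); their entries are replicated across the grid so every cell
    of the output table is fully populated.
    """
    config = config or HuberConfig()
    estimators = tuple(Estimator(e) for e in estimators)
    rng_design = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    X = generate_design(spec.n, spec.p, spec.rho, rng_design)
    beta = true_coefficients(X)
    lambdas, T, Z = _canonical_from_design(X)
    alpha_true = T.T @ beta
    cf = CanonicalForm(lambdas=lambdas, T=T, Z=Z)

    cells = [(k, d) for k in spec.k_grid for d in spec.d_grid]
    sqerr: dict = {(est.value, k, d): np.empty(spec.reps)
                   for est in estimators for (k, d) in cells}
    nonconv = 0
    for rep in range(spec.reps):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1 + rep)))
        if spec.redraw_design:
            X = generate_design(spec.n, spec.p, spec.rho, rng)
            beta = true_coefficients(X)
            lambdas, T, Z = _canonical_from_design(X)
            alpha_true = T.T @ beta
            cf = CanonicalForm(lambdas=lambdas, T=T, Z=Z)
        y = simulate_response(X, beta, spec.sigma, rng)
        y = inject_outliers(y, spec.n_outliers, spec.sigma)
        y = y - y.mean()

        alpha_ols = (Z.T @ y) / lambdas
        alpha_m = None
        if any(e in (Estimator.M, Estimator.RIDGE_M, Estimator.RTMME)
               for e in estimators):
            m_fit = fit_huber_m(cf, y, config)
            alpha_m = m_fit.alpha_hat
            if not m_fit.converged:
                nonconv += 1

        for k, d in cells:
            for est in estimators:
                if est is Estimator.OLS:
                    a = alpha_ols
                elif est is Estimator.M:
                    a = alpha_m
                elif est is Estimator.RIDGE:
                    a = apply_shrinkage(alpha_ols, lambdas, k, 0.0)
                elif est is Estimator.MRT:
                    a = apply_shrinkage(alpha_ols, lambdas, k, d)
                elif est is Estimator.RIDGE_M:
                    a = apply_shrinkage(alpha_m, lambdas, k, 0.0)
                else:
                    a = apply_shrinkage(alpha_m, lambdas, k, d)
                diff = a - alpha_true
                sqerr[(est.value, k, d)][rep] = diff @ diff

    if nonconv > 0.01 * spec.reps:
        warnings.warn(f"IRLS failed to converge in {nonconv}/{spec.reps} replications")

    mse_table, mc_se = {}, {}
    for key, sq in sqerr.items():
        mse_table[key] = float(np.mean(sq))
        mc_se[key] = float(np.std(sq, ddof=1) / np.sqrt(spec.reps)) if spec.reps > 1 else 0.0
    return ScenarioResult(spec=spec, mse_table=mse_table, mc_se=mc_se,
                          true_alpha=alpha_true, nonconverged=nonconv)


def run_grid(specs: list[ScenarioSpec],
             config: HuberConfig | None = None) -> pd.DataFrame:
    """Run a list of scenarios into one long-format table."""
    rows = []
    for spec in specs:
        result = run_scenario(spec, config)
        for (est, k, d), mse in sorted(result.mse_table.items()):
            rows.append({
                "n": spec.n, "p": spec.p, "rho": spec.rho,
                "sigma": spec.sigma, "outliers": spec.n_outliers,
                "k": k, "d": d, "estimator": est,
                "mse": mse, "mc_se": result.mc_se[(est, k, d)],
            })
    return pd.DataFrame(rows)
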