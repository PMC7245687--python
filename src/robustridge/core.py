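"""Design standardization, canonical decomposition, and the base/shrinkage fits.

The linear model is ``y = X beta + eps`` with a centered, unit-column-norm
(correlation-form) design.  Every estimator here is expressed in the
canonical coordinate system obtained by rotating the design with the
eigenvectors ``T`` of ``X'X``, so that ``Z'Z = diag(lambda_1..lambda_p)``.
In those coordinates the whole estimator family is a component-wise
shrinkage of a base fit:

    alpha_shrunk_i = lambda_i / (lambda_i + k (1 + d)) * alpha_base_i

With the OLS base this realizes ridge (``d = 0``) and the modified
ridge-type (MRT) estimator; with the Huber M base it realizes the ridge
M-estimator (``d = 0``) and the two-parameter ridge-type M-estimator
(RTMME).  The ``kd``-scaled modified-ridge variant is the same operator
evaluated at ``(k*d, 0)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Estimator",
    "RegressionData",
    "CanonicalForm",
    "HuberConfig",
    "FitResult",
    "standardize_design",
    "canonical_decompose",
    "fit_ols",
    "fit_huber_m",
    "apply_shrinkage",
    "fit_named",
    "estimate_sigma2",
    "back_transform",
    "huber_psi",
    "huber_psi_prime",
]

_RANK_TOL = 1e-10
# MAD consistency factor for the normal distribution: 1/Phi^{-1}(3/4)
_MAD_NORMAL = 0.6744897501960817
# E|N(0,1)| = sqrt(2/pi); its reciprocal rescales the mean absolute
# residual to a consistent sigma estimate when the MAD degenerates.
_MEANABS_NORMAL = 1.2533141373155003


class Estimator(str, Enum):
    """The six estimators compared throughout the package."""

    OLS = "OLS"
    M = "M"
    RIDGE = "RIDGE"
    RIDGE_M = "RIDGE_M"
    MRT = "MRT"
    RTMME = "RTMME"


#: estimators whose base fit is the Huber M-estimate
_M_BASED = frozenset({Estimator.M, Estimator.RIDGE_M, Estimator.RTMME})


@dataclass
class RegressionData:
    """A standardized (X, y) pair together with the back-transform metadata.

    ``X`` has centered columns scaled to unit Euclidean norm and ``y`` is
    centered; ``column_centers``, ``column_scales`` and ``y_center`` allow
    recovery of raw-scale coefficients and the implied intercept.
    """

    X: np.ndarray
    y: np.ndarray
    n: int
    p: int
    standardized: bool = True
    column_centers: Optional[np.ndarray] = None
    column_scales: Optional[np.ndarray] = None
    y_center: float = 0.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape != (self.n, self.p):
            raise ValueError("X shape inconsistent with (n, p)")
        if self.y.shape != (self.n,):
            raise ValueError("y shape inconsistent with n")
        if not self.n > self.p >= 1:
            raise ValueError("underdetermined: require n > p >= 1")
        sv = np.linalg.svd(self.X, compute_uv=False)
        if sv[-1] <= _RANK_TOL * sv[0]:
            raise ValueError("singular design")


@dataclass
class CanonicalForm:
    """Eigendecomposition of X'X: eigenvalues, rotation and rotated design."""

    lambdas: np.ndarray  # descending eigenvalues of X'X
    T: np.ndarray        # orthogonal eigenvector matrix (columns)
    Z: np.ndarray        # rotated design, Z = X T


@dataclass
class HuberConfig:
    """IRLS settings for the Huber M-fit.

    tuning_c
        Huber tuning constant; 1.345 gives 95% efficiency at the Gaussian.
    scale_rule
        "mad_iterated" re-estimates the MAD scale every iteration;
        "mad_fixed" freezes it at the initial OLS residual scale.
    """

    tuning_c: float = 1.345
    max_iter: int = 100
    tol: float = 1e-8
    scale_rule: str = "mad_iterated"

    def __post_init__(self) -> None:
        if self.tuning_c <= 0:
            raise ValueError("tuning_c must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.scale_rule not in ("mad_iterated", "mad_fixed"):
            raise ValueError(f"unknown scale_rule {self.scale_rule!r}")


@dataclass
class FitResult:
    """A fitted coefficient vector in both canonical and original scale."""

    estimator: Estimator
    alpha_hat: np.ndarray
    beta_hat: np.ndarray
    k: float = 0.0
    d: float = 0.0
    scale_s: Optional[float] = None
    weights: Optional[np.ndarray] = None
    converged: bool = True
    iterations: int = 0
    scale_fallback: bool = False


def _standardize_columns(X_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center columns and scale each to unit Euclidean norm."""
    X_raw = np.asarray(X_raw, dtype=float)
    centers = X_raw.mean(axis=0)
    Xc = X_raw - centers
    scales = np.linalg.norm(Xc, axis=0)
    if np.any(scales <= 0):
        raise ValueError("zero-variance column")
    return Xc / scales, centers, scales


def standardize_design(X_raw: np.ndarray, y_raw: np.ndarray) -> RegressionData:
    """Put raw data into correlation form: unit-norm centered X, centered y."""
    X_raw = np.asarray(X_raw, dtype=float)
    y_raw = np.asarray(y_raw, dtype=float)
    if X_raw.ndim != 2:
        raise ValueError("X_raw must be 2-dimensional")
    n, p = X_raw.shape
    if n <= p:
        raise ValueError("underdetermined: require n > p")
    if np.isnan(X_raw).any() or np.isnan(y_raw).any():
        raise ValueError("missing values in input")
    X, centers, scales = _standardize_columns(X_raw)
    y_center = float(y_raw.mean())
    return RegressionData(
        X=X, y=y_raw - y_center, n=n, p=p, standardized=True,
        column_centers=centers, column_scales=scales, y_center=y_center,
    )


def canonical_decompose(data: RegressionData) -> CanonicalForm:
    """Rotate the design into the eigenbasis of X'X.

    Eigenvalues come out descending; each eigenvector's first entry of
    magnitude above tolerance is made positive so the rotation is
    reproducible across platforms.
    """
    XtX = data.X.T @ data.X
    evals, evecs = np.linalg.eigh(XtX)
    order = np.argsort(evals, kind="stable")[::-1]
    lambdas = evals[order]
    T = evecs[:, order]
    if lambdas[-1] <= _RANK_TOL * lambdas[0]:
        raise ValueError("effectively singular")
    # deterministic sign convention
    for j in range(T.shape[1]):
        col = T[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            T[:, j] = -col
    return CanonicalForm(lambdas=lambdas, T=T, Z=data.X @ T)


def fit_ols(cf: CanonicalForm, y: np.ndarray) -> FitResult:
    """Ordinary least squares in canonical coordinates: alpha = Lambda^-1 Z'y."""
    alpha = (cf.Z.T @ y) / cf.lambdas
    return FitResult(Estimator.OLS, alpha_hat=alpha, beta_hat=cf.T @ alpha)


def huber_psi(u: np.ndarray, c: float) -> np.ndarray:
    """Huber score function: identity inside [-c, c], clipped outside."""
    return np.clip(u, -c, c)


def huber_psi_prime(u: np.ndarray, c: float) -> np.ndarray:
    """Derivative of the Huber score: 1 inside the band, 0 outside."""
    return (np.abs(u) <= c).astype(float)


def _robust_scale(e: np.ndarray) -> tuple[float, bool]:
    """MAD-based scale of residuals (about zero); fallback to rescaled
    mean absolute residual when the MAD degenerates to zero."""
    mad = float(np.median(np.abs(e)))
    if mad > 0:
        return mad / _MAD_NORMAL, False
    return float(np.mean(np.abs(e))) * _MEANABS_NORMAL, True


def fit_huber_m(cf: CanonicalForm, y: np.ndarray,
                config: Optional[HuberConfig] = None) -> FitResult:
    """Huber M-estimate by iteratively reweighted least squares.

    Solves sum_i psi(e_i / s) z_i = 0 with psi the Huber score, starting
    at the OLS fit.  The weights at the solution are
    ``w_i = min(1, c * s / |e_i|)``.
    """
    config = config or HuberConfig()
    c = config.tuning_c
    Z, lambdas = cf.Z, cf.lambdas
    n = Z.shape[0]
    alpha = (Z.T @ y) / lambdas
    e = y - Z @ alpha
    s, fallback = _robust_scale(e)
    y_mag = float(np.linalg.norm(y)) + 1.0
    if s <= 1e-13 * y_mag:
        # exact (or numerically exact) interpolation: psi equations hold trivially
        return FitResult(Estimator.M, alpha_hat=alpha, beta_hat=cf.T @ alpha,
                         scale_s=s, weights=np.ones(n), converged=True,
                         iterations=0, scale_fallback=fallback)
    if config.scale_rule == "mad_fixed":
        s_fixed = s
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        if config.scale_rule == "mad_iterated":
            s, fallback = _robust_scale(e)
            if s <= 1e-13 * y_mag:
                converged = True
                break
        else:
            s = s_fixed
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, c * s / np.abs(e))
        w[e == 0] = 1.0
        Zw = Z * w[:, None]
        alpha_new = np.linalg.solve(Z.T @ Zw, Zw.T @ y)
        step = np.max(np.abs(alpha_new - alpha))
        alpha = alpha_new
        e = y - Z @ alpha
        if step / (1.0 + np.max(np.abs(alpha))) < config.tol:
            converged = True
            break
    with np.errstate(divide="ignore"):
        w = np.minimum(1.0, c * s / np.abs(e))
    w[e == 0] = 1.0
    return FitResult(Estimator.M, alpha_hat=alpha, beta_hat=cf.T @ alpha,
                     scale_s=float(s), weights=w, converged=converged,
                     iterations=it, scale_fallback=fallback)


def apply_shrinkage(alpha_base: np.ndarray, lambdas: np.ndarray,
                    k: float, d: float) -> np.ndarray:
    """Component-wise shrinkage lambda_i/(lambda_i + k(1+d)) * alpha_base_i."""
    if k < 0 or d < 0:
        raise ValueError("invalid biasing parameter")
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas <= 0):
        raise ValueError("eigenvalues must be positive")
    return lambdas / (lambdas + k * (1.0 + d)) * np.asarray(alpha_base, dtype=float)


def _shrunk_result(base: FitResult, cf: CanonicalForm, estimator: Estimator,
                   k: float, d: float) -> FitResult:
    alpha = apply_shrinkage(base.alpha_hat, cf.lambdas, k, d)
    return FitResult(estimator, alpha_hat=alpha, beta_hat=cf.T @ alpha,
                     k=float(k), d=float(d), scale_s=base.scale_s,
                     weights=base.weights, converged=base.converged,
                     iterations=base.iterations, scale_fallback=base.scale_fallback)


def fit_named(estimator: Estimator | str, data: RegressionData,
              k: float = 0.0, d: float = 0.0,
              config: Optional[HuberConfig] = None,
              cf: Optional[CanonicalForm] = None) -> FitResult:
    """Fit any of the six estimators on standardized data.

    ``k`` is ignored for OLS/M; ``d`` is ignored for RIDGE/RIDGE_M.  A
    precomputed :class:`CanonicalForm` may be passed to amortize the
    eigendecomposition across fits on the same design.
    """
    estimator = Estimator(estimator)
    if cf is None:
        cf = canonical_decompose(data)
    y = data.y
    if estimator is Estimator.OLS:
        return fit_ols(cf, y)
    if estimator is Estimator.M:
        return fit_huber_m(cf, y, config)
    if estimator is Estimator.RIDGE:
        return _shrunk_result(fit_ols(cf, y), cf, estimator, k, 0.0)
    if estimator is Estimator.MRT:
        return _shrunk_result(fit_ols(cf, y), cf, estimator, k, d)
    base = fit_huber_m(cf, y, config)
    if estimator is Estimator.RIDGE_M:
        return _shrunk_result(base, cf, estimator, k, 0.0)
    if estimator is Estimator.RTMME:
        return _shrunk_result(base, cf, estimator, k, d)
    raise ValueError(f"unknown estimator {estimator!r}")


def estimate_sigma2(cf: CanonicalForm, y: np.ndarray) -> float:
    """Unbiased OLS error-variance estimate RSS / (n - p)."""
    n, p = cf.Z.shape
    alpha = (cf.Z.T @ y) / cf.lambdas
    r = y - cf.Z @ alpha
    return float(r @ r) / (n - p)


def back_transform(fit: FitResult, data: RegressionData) -> tuple[np.ndarray, float]:
    """Map standardized-scale coefficients back to the raw data scale.

    Returns ``(beta_raw, intercept)`` such that
    ``intercept + X_raw @ beta_raw`` reproduces the standardized-model
    fitted values (plus the response center).
    """
    if not data.standardized or data.column_scales is None:
        raise ValueError("missing standardization metadata")
    beta_raw = fit.beta_hat / data.column_scales
    intercept = data.y_center - float(data.column_centers @ beta_raw)
    return beta_raw, intercept
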