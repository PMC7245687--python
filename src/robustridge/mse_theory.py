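"""Closed-form scalar MSE expressions and the estimator-comparison theory.

In canonical coordinates the scalar mean squared error
``E[(alpha_hat - alpha)'(alpha_hat - alpha)]`` of each estimator in the
family has a closed form in terms of the eigenvalues ``lambda_i``, the
true coefficients ``alpha_i``, the error variance ``sigma^2`` and the
diagonal ``Omega_ii`` of the asymptotic covariance of the canonical
M-estimate.  This module evaluates those forms, the pairwise difference
functions used to compare RTMME against MRT, the ridge M-estimator and
the plain M-estimator, and the biasing-parameter threshold below which
RTMME cannot dominate the ridge M-estimator.

The printed threshold formula and the quadratic inequality it is derived
from are not mutually consistent; both closed forms are exposed
(:func:`k1_threshold`, :func:`k1_threshold_quadratic`) alongside an
independent numeric sign-change locator (:func:`sign_change_points`) so
the disagreement can be quantified rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import Estimator

__all__ = [
    "TheoreticalSetting",
    "theoretical_mse",
    "delta_rtmme_vs_mrt",
    "delta_rtmme_vs_ridgem",
    "delta_rtmme_vs_m",
    "k1_threshold",
    "k1_threshold_quadratic",
    "sign_change_points",
    "check_theorem1",
    "check_theorem3",
]


@dataclass
class TheoreticalSetting:
    """Argument list of the closed-form MSE expressions.

    omega_diag is the diagonal of Omega = Cov(alpha_hat_M); for a Huber
    fit it is asymptotically A^2 / lambda_i.
    """

    lambdas: np.ndarray
    alpha: np.ndarray
    sigma2: float
    omega_diag: np.ndarray
    k: float = 0.0
    d: float = 0.0

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.omega_diag = np.asarray(self.omega_diag, dtype=float)
        p = self.lambdas.shape[0]
        if self.alpha.shape != (p,) or self.omega_diag.shape != (p,):
            raise ValueError("vector lengths disagree")
        if np.any(self.lambdas <= 0):
            raise ValueError("lambdas must be positive")
        if self.sigma2 < 0 or np.any(self.omega_diag < 0):
            raise ValueError("variances must be non-negative")


def theoretical_mse(estimator: Estimator | str, s: TheoreticalSetting) -> float:
    """Closed-form scalar MSE of one estimator at a theoretical setting."""
    estimator = Estimator(estimator)
    lam, a, k, d = s.lambdas, s.alpha, s.k, s.d
    if estimator is Estimator.OLS:
        return float(s.sigma2 * np.sum(1.0 / lam))
    if estimator is Estimator.M:
        return float(np.sum(s.omega_diag))
    if estimator is Estimator.RIDGE:
        den = (lam + k) ** 2
        return float(np.sum((s.sigma2 * lam + k**2 * a**2) / den))
    if estimator is Estimator.RIDGE_M:
        den = (lam + k) ** 2
        return float(np.sum((lam**2 * s.omega_diag + k**2 * a**2) / den))
    kd = k * (1.0 + d)
    den = (lam + kd) ** 2
    if estimator is Estimator.MRT:
        return float(np.sum((s.sigma2 * lam + kd**2 * a**2) / den))
    if estimator is Estimator.RTMME:
        return float(np.sum((lam**2 * s.omega_diag + kd**2 * a**2) / den))
    raise ValueError(f"unknown estimator {estimator!r}")


def delta_rtmme_vs_mrt(s: TheoreticalSetting) -> float:
    """MSE(RTMME) - MSE(MRT): sum lam_i (lam_i Omega_ii - sigma^2) / (lam_i + k(1+d))^2."""
    kd = s.k * (1.0 + s.d)
    return float(np.sum(s.lambdas * (s.lambdas * s.omega_diag - s.sigma2)
                        / (s.lambdas + kd) ** 2))


def delta_rtmme_vs_ridgem(s: TheoreticalSetting) -> float:
    """MSE(RTMME) - MSE(ridge-M); identically zero at d = 0 or k = 0."""
    lam, a, om = s.lambdas, s.alpha, s.omega_diag
    kd = s.k * (1.0 + s.d)
    t_rtmme = np.sum((lam**2 * om + kd**2 * a**2) / (lam + kd) ** 2)
    t_rm = np.sum((lam**2 * om + s.k**2 * a**2) / (lam + s.k) ** 2)
    return float(t_rtmme - t_rm)


def delta_rtmme_vs_m(s: TheoreticalSetting) -> float:
    """MSE(RTMME) - MSE(M), as a difference of the closed-form sums."""
    lam, a, om = s.lambdas, s.alpha, s.omega_diag
    kd = s.k * (1.0 + s.d)
    return float(np.sum((lam**2 * om + kd**2 * a**2) / (lam + kd) ** 2) - np.sum(om))


def delta_rtmme_vs_m_components(s: TheoreticalSetting) -> np.ndarray:
    """Per-component form of MSE(RTMME) - MSE(M):
    [-Omega_ii (2 lam_i k(1+d) + k^2(1+d)^2) + k^2(1+d)^2 alpha_i^2] / (lam_i + k(1+d))^2.
    """
    lam, a, om = s.lambdas, s.alpha, s.omega_diag
    kd = s.k * (1.0 + s.d)
    num = -om * (2 * lam * kd + kd**2) + kd**2 * a**2
    return num / (lam + kd) ** 2


def k1_threshold(lambda_i: float, alpha_i2: float, omega_ii: float, d: float) -> float:
    """Printed closed-form threshold k_1i for RTMME to beat the ridge M-estimator.

    k_1i = lam [sqrt((d + 2a^2 - W)^2 + 8 a^2 W (d+1)) - (d + 2a^2 - W)] / (4 a^2 (d+1))
    with a^2 = alpha_i^2 and W = Omega_ii.
    """
    if alpha_i2 <= 0:
        raise ValueError("degenerate component")
    if lambda_i <= 0 or omega_ii < 0 or d < 0:
        raise ValueError("invalid setting")
    b = d + 2.0 * alpha_i2 - omega_ii
    rad = np.sqrt(b**2 + 8.0 * alpha_i2 * omega_ii * (d + 1.0))
    return float(lambda_i * (rad - b) / (4.0 * alpha_i2 * (d + 1.0)))


def k1_threshold_quadratic(lambda_i: float, alpha_i2: float, omega_ii: float,
                           d: float) -> float:
    """Positive root of the quadratic inequality the threshold derives from:
    2 a^2 k^2 + lam (d + 2a^2 - W) k - 2 W lam^2 < 0, i.e.
    k_1i = lam [sqrt((d + 2a^2 - W)^2 + 16 a^2 W) - (d + 2a^2 - W)] / (4 a^2).
    """
    if alpha_i2 <= 0:
        raise ValueError("degenerate component")
    b = d + 2.0 * alpha_i2 - omega_ii
    rad = np.sqrt(b**2 + 16.0 * alpha_i2 * omega_ii)
    return float(lambda_i * (rad - b) / (4.0 * alpha_i2))


def sign_change_points(s: TheoreticalSetting, k_max: float,
                       n_grid: int = 1000) -> list[float]:
    """Numerically locate all sign changes of k -> MSE(RTMME)-MSE(ridge-M).

    Scans a log-spaced grid on (0, k_max] and refines each bracketed sign
    change by bisection to 1e-10.  Returns an empty list when the
    difference never changes sign (in particular identically-zero d = 0).
    """
    if k_max <= 0:
        raise ValueError("k_max must be > 0")
    if s.d == 0:
        return []

    def f(k: float) -> float:
        return delta_rtmme_vs_ridgem(
            TheoreticalSetting(s.lambdas, s.alpha, s.sigma2, s.omega_diag, k, s.d))

    ks = np.logspace(np.log10(k_max) - 8, np.log10(k_max), n_grid)
    vals = np.array([f(k) for k in ks])
    roots: list[float] = []
    for i in range(len(ks) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            continue
        if np.sign(a) != np.sign(b):
            if b == 0.0:
                roots.append(float(ks[i + 1]))
            else:
                roots.append(float(brentq(f, ks[i], ks[i + 1], xtol=1e-10)))
    return roots


def check_theorem1(s: TheoreticalSetting) -> dict:
    """Evidence record for the RTMME-vs-MRT comparison.

    The sum-level condition (sum Omega_ii < sum sigma^2/lambda_i) and the
    componentwise condition (Omega_ii < sigma^2/lambda_i for every i) are
    reported separately: only the componentwise one guarantees a negative
    difference for all k > 0, d >= 0.
    """
    sum_cond = bool(np.sum(s.omega_diag) < s.sigma2 * np.sum(1.0 / s.lambdas))
    comp_cond = bool(np.all(s.omega_diag < s.sigma2 / s.lambdas))
    return {
        "sum_condition": sum_cond,
        "componentwise_condition": comp_cond,
        "delta1": delta_rtmme_vs_mrt(s),
    }


def check_theorem3(s: TheoreticalSetting) -> dict:
    """Raw quantities for the RTMME-vs-M necessary condition.

    Reports the bound sum k(1+d) alpha_i^2 / (2 lambda_i + k(1+d)), the
    Omega trace, and the realized difference; no inequality is asserted
    because the stated direction of the condition and the one its
    derivation ends with disagree.
    """
    kd = s.k * (1.0 + s.d)
    bound = float(np.sum(kd * s.alpha**2 / (2.0 * s.lambdas + kd)))
    return {
        "bound": bound,
        "omega_sum": float(np.sum(s.omega_diag)),
        "delta3": delta_rtmme_vs_m(s),
    }
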