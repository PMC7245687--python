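"""Robust selection of the biasing parameters k and d.

The selection rules plug robust estimates into the minimizers of the
theoretical RTMME risk.  The variance statistic

    A^2 = s^2/(n-p-1) * sum psi(e_i/s)^2 / [ (1/n) sum psi'(e_i/s) ]^2

(summed over all n residuals of the converged M-fit) estimates the
asymptotic variance factor of the canonical Huber M-estimate, so that
Omega_ii is estimated by A^2 / lambda_i and alpha_i^2 by the squared
M-coefficients.  The per-component optima

    d_i = A^2 / (k alpha_Mi^2) - 1,      k_i = A^2 / ((1+d) alpha_Mi^2)

are aggregated by harmonic (HMR), geometric (GMR) or arithmetic (AMR)
means; the harmonic versions drive the iterative procedure:

    Step 1: d0 = min_i A^2 / alpha_Mi^2
    Step 2: k  = HMR rule at d0
    Step 3: d  = harmonic mean of the d_i at that k
    Step 4: fall back to d0 if Step 3 turned negative
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    CanonicalForm,
    HuberConfig,
    RegressionData,
    canonical_decompose,
    fit_huber_m,
    huber_psi,
    huber_psi_prime,
)

__all__ = [
    "SelectionResult",
    "estimate_A2",
    "estimate_omega_diag",
    "d_initial",
    "k_robust",
    "d_hmr",
    "kd_steps",
    "select_kd",
]


@dataclass
class SelectionResult:
    """Outcome of the k/d selection procedure, with a full step trace."""

    A2: float
    omega_diag: np.ndarray
    d_init: float
    k_hmr: float
    d_hmr: float
    k_gmr: float
    k_amr: float
    k_final: float
    d_final: float
    used_fallback: bool
    trace: list = field(default_factory=list)


def estimate_A2(residuals: np.ndarray, scale_s: float, n: int, p: int,
                config: Optional[HuberConfig] = None) -> float:
    """Huber's variance statistic A^2 from the converged M-fit residuals."""
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    if scale_s <= 0:
        raise ValueError("scale_s must be > 0")
    config = config or HuberConfig()
    u = np.asarray(residuals, dtype=float) / scale_s
    psi = huber_psi(u, config.tuning_c)
    dpsi_mean = float(np.mean(huber_psi_prime(u, config.tuning_c)))
    if dpsi_mean == 0.0:
        raise ValueError("degenerate psi-derivative sum")
    return float(scale_s**2 / (n - p - 1) * np.sum(psi**2) / dpsi_mean**2)


def estimate_omega_diag(A2: float, lambdas: np.ndarray) -> np.ndarray:
    """Asymptotic diagonal of Cov(alpha_hat_M): A^2 / lambda_i."""
    if A2 < 0:
        raise ValueError("A2 must be >= 0")
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas <= 0):
        raise ValueError("lambdas must be positive")
    return A2 / lambdas


def d_initial(A2: float, alpha_m: np.ndarray) -> float:
    """Step-1 initial d: min_i A^2 / alpha_Mi^2."""
    alpha_m = np.asarray(alpha_m, dtype=float)
    if np.any(alpha_m == 0):
        raise ValueError("degenerate coefficient for d initialization")
    return float(np.min(A2 / alpha_m**2))


def k_robust(rule: str, A2: float, d: float, alpha_m: np.ndarray) -> float:
    """Aggregate the per-component optimal k by HMR/GMR/AMR means."""
    alpha_m = np.asarray(alpha_m, dtype=float)
    if A2 <= 0:
        raise ValueError("A2 must be > 0")
    if d < 0:
        raise ValueError("d must be >= 0")
    if np.any(alpha_m == 0):
        raise ValueError("degenerate coefficient")
    a2 = alpha_m**2
    p = a2.shape[0]
    if rule == "HMR":
        return float(p * A2 / np.sum((1.0 + d) * a2))
    if rule == "GMR":
        return float(np.exp(np.mean(np.log(A2 / ((1.0 + d) * a2)))))
    if rule == "AMR":
        return float(np.mean(A2 / ((1.0 + d) * a2)))
    raise ValueError(f"unknown rule {rule!r}")


def d_hmr(k: float, A2: float, alpha_m: np.ndarray) -> float:
    """Harmonic mean of the per-component d_i = A^2/(k alpha_Mi^2) - 1.

    May be negative; the Step-4 fallback upstream handles that case.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    alpha_m = np.asarray(alpha_m, dtype=float)
    if np.any(alpha_m == 0):
        raise ValueError("degenerate coefficient")
    di = A2 / (k * alpha_m**2) - 1.0
    if np.any(di == 0):
        raise ValueError("harmonic mean undefined")
    p = di.shape[0]
    return float(p / np.sum(1.0 / di))


def kd_steps(A2: float, alpha_m: np.ndarray) -> SelectionResult:
    """Run selection Steps 1-4 given A^2 and the canonical M-coefficients."""
    trace: list = []
    d0 = d_initial(A2, alpha_m)
    trace.append(("step1_d_init", d0))
    k = k_robust("HMR", A2, d0, alpha_m)
    trace.append(("step2_k_hmr", k))
    d_tilde = d_hmr(k, A2, alpha_m)
    trace.append(("step3_d_hmr", d_tilde))
    used_fallback = d_tilde < 0
    d_final = d0 if used_fallback else d_tilde
    trace.append(("step4_d_final", d_final))
    if k <= 0:
        raise ValueError("selected k is not positive")
    return SelectionResult(
        A2=A2,
        omega_diag=np.empty(0),
        d_init=d0,
        k_hmr=k,
        d_hmr=d_tilde,
        k_gmr=k_robust("GMR", A2, d0, alpha_m),
        k_amr=k_robust("AMR", A2, d0, alpha_m),
        k_final=k,
        d_final=d_final,
        used_fallback=used_fallback,
        trace=trace,
    )


def select_kd(data: RegressionData, config: Optional[HuberConfig] = None,
              clip_d: bool = False,
              cf: Optional[CanonicalForm] = None) -> SelectionResult:
    """End-to-end k/d selection: Huber fit, A^2, then Steps 1-4.

    The selected d can exceed 1 (the iterative rules never clip); a
    warning is emitted in that case, and ``clip_d=True`` caps the final d
    at 1 for users wanting the theoretical 0 < d < 1 range.
    """
    config = config or HuberConfig()
    if cf is None:
        cf = canonical_decompose(data)
    m_fit = fit_huber_m(cf, data.y, config)
    if not m_fit.converged:
        warnings.warn("M-fit did not converge; selection uses last iterate")
    residuals = data.y - cf.Z @ m_fit.alpha_hat
    A2 = estimate_A2(residuals, m_fit.scale_s, data.n, data.p, config)
    result = kd_steps(A2, m_fit.alpha_hat)
    result.omega_diag = estimate_omega_diag(A2, cf.lambdas)
    if result.d_final > 1.0:
        if clip_d:
            result.trace.append(("clip_d", 1.0))
            result.d_final = 1.0
        else:
            warnings.warn(f"selected d = {result.d_final:.4g} exceeds 1")
    return result
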