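"""Mediation-proportion estimates with variances.

For likelihood methods, Var(alpha_hat) and Var(omega_hat) come from the
likelihood-ratio test via the Wald correspondence Var(est) = est^2 / chi2,
with Var(theta_hat) = Var(alpha_hat) + Var(omega_hat). For a single
exposure-outcome pair MP_hat = 1 - alpha_hat/theta_hat with the delta-method
variance (no covariance term); for a group of pairs MP_hat comes from the
no-intercept regression of the direct on the total effects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

Z95 = 1.959963984540054


@dataclass
class MPEstimate:
    """Mediation proportion, its variance, and a normal-approximation CI."""

    mp_hat: float
    var_mp: float
    n_pairs: int
    method: str = ""
    defined: bool = True
    n_excluded: int = 0

    @property
    def se(self) -> float:
        return math.sqrt(self.var_mp) if self.var_mp >= 0 else math.nan

    @property
    def ci(self) -> tuple[float, float]:
        half = Z95 * self.se
        return (self.mp_hat - half, self.mp_hat + half)

    def ci_excludes_zero(self) -> bool:
        lo, hi = self.ci
        return lo > 0 or hi < 0

    def ci_contains(self, value: float) -> bool:
        lo, hi = self.ci
        return lo <= value <= hi

    def to_json(self) -> str:
        lo, hi = self.ci
        return json.dumps({
            "mp_hat": self.mp_hat, "var_mp": self.var_mp,
            "ci95": [lo, hi], "n_pairs": self.n_pairs, "method": self.method,
            "defined": bool(self.defined), "n_excluded": self.n_excluded,
        })


def lrt_variances(alpha_hat: float, omega_hat: float, loglik_ao):
    """LRT-based variances of the ML estimates.

    ``loglik_ao(alpha, omega)`` is the profile log-likelihood. The LRT
    statistics chi2_alpha = -2 log[L(0, omega_hat)/L(alpha_hat, omega_hat)]
    and chi2_omega (analogously with omega = 0) give
    Var(est) = est^2 / chi2; an estimate exactly at its null yields an
    infinite variance (zero Wald statistic), reported as such.

    Returns (var_alpha, var_omega, var_theta, chi2_alpha, chi2_omega).
    """
    ll_full = loglik_ao(alpha_hat, omega_hat)
    chi2_a = max(0.0, -2.0 * (loglik_ao(0.0, omega_hat) - ll_full))
    chi2_w = max(0.0, -2.0 * (loglik_ao(alpha_hat, 0.0) - ll_full))
    var_a = alpha_hat**2 / chi2_a if chi2_a > 0 else math.inf
    var_w = omega_hat**2 / chi2_w if chi2_w > 0 else math.inf
    return var_a, var_w, var_a + var_w, chi2_a, chi2_w


def mp_single(alpha_hat: float, theta_hat: float, var_alpha: float,
              var_theta: float, method: str = "") -> MPEstimate:
    """Single-pair MP with the delta-method variance as printed.

    Var(MP) = (alpha^2/theta^2) (Var(alpha)/alpha^2 + Var(theta)/theta^2);
    the covariance of alpha_hat and theta_hat is deliberately omitted. A
    zero total effect yields an undefined result rather than an exception.
    """
    if theta_hat == 0:
        return MPEstimate(mp_hat=math.nan, var_mp=math.inf, n_pairs=1,
                          method=method, defined=False)
    mp = 1.0 - alpha_hat / theta_hat
    ratio2 = alpha_hat**2 / theta_hat**2
    if alpha_hat == 0:
        var = 0.0 if math.isfinite(var_theta) else math.nan
    else:
        var = ratio2 * (var_alpha / alpha_hat**2 + var_theta / theta_hat**2)
    defined = 0.0 <= mp <= 1.0 and np.sign(alpha_hat) == np.sign(theta_hat)
    return MPEstimate(mp_hat=mp, var_mp=var, n_pairs=1, method=method,
                      defined=bool(defined))


def mp_group(alpha_hats, theta_hats, method: str = "",
             n_excluded: int = 0) -> MPEstimate:
    """Group MP from the no-intercept regression of alpha on theta.

    MP_hat = 1 - sum(alpha_i theta_i)/sum(theta_i^2) and
    Var(MP_hat) = sigma^2 / sum(theta_i^2) with sigma^2 the residual
    variance (RSS/(n-1); one slope parameter, no intercept).
    """
    a = np.asarray(alpha_hats, dtype=float)
    t = np.asarray(theta_hats, dtype=float)
    if a.shape != t.shape or a.ndim != 1:
        raise ValueError("alpha_hats and theta_hats must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("group MP needs at least two pairs")
    stt = float(t @ t)
    if stt == 0:
        return MPEstimate(mp_hat=math.nan, var_mp=math.inf, n_pairs=n,
                          method=method, defined=False, n_excluded=n_excluded)
    slope = float(a @ t) / stt
    mp = 1.0 - slope
    resid = a - slope * t
    sigma2 = float(resid @ resid) / (n - 1)
    var = sigma2 / stt
    defined = 0.0 <= mp <= 1.0
    return MPEstimate(mp_hat=mp, var_mp=var, n_pairs=n, method=method,
                      defined=bool(defined), n_excluded=n_excluded)
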