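"""Two-step Mendelian-randomization baseline: IVW and block-matrix MVMR.

The total causal effect theta is estimated by univariable inverse-variance
weighted (IVW) MR from the exposure instruments; the direct effect alpha by
multivariable MR (MVMR) on the stacked design of exposure and mediator
instruments with the mediator-instrument-on-exposure block fixed at zero.
Both are weighted least squares and inherit the OLS assumption that the
regressors (the estimated instrument effects) are error-free, which is the
source of the regression-dilution bias this package quantifies.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass
from scipy import stats
from sklearn.base import BaseEstimator

from .data import FitResult, SummaryData


class SingularDesignError(np.linalg.LinAlgError):
    """The (weighted) design matrix is rank deficient."""


@dataclass
class IVWResult:
    estimate: float
    variance: float
    n_instruments: int
    p_value: float


@dataclass
class MVMRResult:
    alpha_hat: float
    delta_hat: np.ndarray
    var_alpha: float
    cov: np.ndarray  # covariance of (alpha_hat, delta_hat)


def _wls(design: np.ndarray, response: np.ndarray, weights_var: np.ndarray,
         label_cols=None):
    """Weighted least squares with explicit singularity detection."""
    w = 1.0 / weights_var
    xtw = design.T * w
    xtwx = xtw @ design
    xtwy = xtw @ response
    rank = np.linalg.matrix_rank(xtwx)
    if rank < design.shape[1]:
        _, _, vt = np.linalg.svd(xtwx)
        worst = np.argsort(np.abs(vt[-1]))[::-1][:3]
        names = (list(np.asarray(label_cols)[worst]) if label_cols is not None
                 else list(map(int, worst)))
        raise SingularDesignError(
            f"design is rank deficient (rank {rank} < {design.shape[1]}); "
            f"columns involved: {names}")
    cov = np.linalg.inv(xtwx)
    return cov @ xtwy, cov


def ivw_total_effect(beta_hat, c_hat, var_c, ld=None) -> IVWResult:
    """Univariable IVW MR of the outcome on the exposure instruments.

    With a single instrument this reduces to the Wald ratio c/beta with the
    first-order Taylor variance Var(c)/beta^2. ``ld`` optionally replaces the
    diagonal weight matrix with a full instrument-correlation matrix.
    """
    beta_hat = np.atleast_1d(np.asarray(beta_hat, dtype=float))
    c_hat = np.atleast_1d(np.asarray(c_hat, dtype=float))
    var_c = np.broadcast_to(np.asarray(var_c, dtype=float), beta_hat.shape)
    if np.all(beta_hat == 0):
        raise SingularDesignError("all exposure instrument effects are zero")
    if ld is not None:
        winv = np.linalg.inv(np.asarray(ld, dtype=float))
        denom = float(beta_hat @ winv @ beta_hat)
        est = float(beta_hat @ winv @ c_hat) / denom
        var = 1.0 / denom
    else:
        coef, cov = _wls(beta_hat[:, None], c_hat, var_c)
        est, var = float(coef[0]), float(cov[0, 0])
    p = float(stats.chi2.sf(est**2 / var, df=1))
    return IVWResult(estimate=est, variance=var,
                     n_instruments=beta_hat.size, p_value=p)


def mvmr_direct_effect(data: SummaryData, ld=None) -> MVMRResult:
    """Block-matrix IVW MVMR for the direct effect and mediator effects.

    Solves the weighted regression of (c_hat, b_hat) on the stacked design
    [[beta_hat, C_hat], [0, B_hat]]; the zero block encodes the framework
    assumption that mediator instruments have no effect on the exposure.
    """
    m, k, l = data.m, data.k, data.l
    design = np.zeros((m + l, k + 1))
    design[:m, 0] = data.beta_hat
    if k:
        design[:m, 1:] = data.C_hat
        design[m:, 1:] = data.B_hat
    response = np.concatenate([data.c_hat, data.b_hat])
    if ld is not None:
        winv = np.linalg.inv(np.asarray(ld, dtype=float))
        xtwx = design.T @ winv @ design
        if np.linalg.matrix_rank(xtwx) < k + 1:
            raise SingularDesignError("design is rank deficient under the LD weights")
        cov = np.linalg.inv(xtwx)
        coef = cov @ design.T @ winv @ response
    else:
        weights_var = np.concatenate([data.var_c, data.var_b])
        labels = ["exposure"] + [f"M{j + 1}" for j in range(k)]
        coef, cov = _wls(design, response, weights_var, label_cols=labels)
    return MVMRResult(alpha_hat=float(coef[0]), delta_hat=coef[1:].copy(),
                      var_alpha=float(cov[0, 0]), cov=cov)


def ivw_gamma(data: SummaryData) -> np.ndarray:
    """Column-wise IVW exposure->mediator effects (used as warm starts)."""
    btb = float(data.beta_hat @ data.beta_hat)
    return data.beta_hat @ data.C_hat / btb


class TwoStepMR(BaseEstimator):
    """Two-step MR+MVMR mediation estimator.

    ``fit`` computes theta from univariable IVW, alpha from MVMR, and
    omega = theta - alpha. Var(omega) = Var(theta) + Var(alpha): the two
    steps use different regressions, so their covariance is not available
    and is ignored (documented limitation).

    Parameters
    ----------
    ld : array-like, optional
        Full instrument correlation matrix replacing the diagonal weights
        (exposed for correlated-instrument data; untested at scale).
    """

    def __init__(self, ld=None):
        self.ld = ld

    def fit(self, data: SummaryData, y=None):
        ivw = ivw_total_effect(data.beta_hat, data.c_hat, data.var_c,
                               ld=None if self.ld is None else np.asarray(self.ld)[:data.m, :data.m])
        mv = mvmr_direct_effect(data, ld=self.ld)
        self.theta_ = ivw.estimate
        self.var_theta_ = ivw.variance
        self.alpha_ = mv.alpha_hat
        self.var_alpha_ = mv.var_alpha
        self.delta_ = mv.delta_hat
        self.gamma_ = ivw_gamma(data)
        self.omega_ = self.theta_ - self.alpha_
        self.var_omega_ = self.var_theta_ + self.var_alpha_
        self.converged_ = True
        self.result_ = FitResult(
            method="mr_mvmr", alpha=self.alpha_, omega=self.omega_,
            gamma=self.gamma_, delta=self.delta_,
            var_alpha=self.var_alpha_, var_omega=self.var_omega_,
            var_theta=self.var_theta_, converged=True, n_mediators=data.k,
            extras={"ivw_p_value": ivw.p_value},
        )
        return self


def mr_mvmr_mediation(data: SummaryData, ld=None) -> FitResult:
    """Functional wrapper over :class:`TwoStepMR`."""
    return TwoStepMR(ld=ld).fit(data).result_
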