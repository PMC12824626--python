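"""Generative model for ground-truth mediation models and summary statistics.

One replicate is built in four stages:

1. mediation effects (gamma_i, delta_i) from a Gaussian spike-and-slab whose
   slab covariance is solved from (MP, E(theta), sigma2_YM, rho_gd, k_s);
2. the direct effect alpha, fixed so that 1 - alpha/theta = MP exactly
   (or drawn uniformly around E(theta) when MP = 0);
3. instrument effects beta and B, scaled post hoc so that the exposure
   heritability and per-mediator heritabilities hold exactly;
4. noisy summary statistics with Gaussian estimation error scaled by the
   study sample sizes, correlated across mediators through the phenotypic
   correlation matrix Sigma (applied via its Cholesky factor).

The module also implements IVW-based mediator selection, which the simulation
study applies before fitting any estimator.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .data import (
    DegenerateModelError,
    GeneticArchitecture,
    InvalidParameterError,
    Scenario,
    SummaryData,
    TrueEffects,
)

WEIBULL_SHAPE = 0.5
WEIBULL_SCALE = 0.05


def solve_prior_variances(mp, expected_theta, sigma2_YM, rho_gd, k_s):
    """Solve the slab covariance of the mediation effects.

    Returns (sigma2_g, sigma2_d, sigma_gd) such that with k_s i.i.d. slab
    draws, E(omega) = k_s*sigma_gd and
    E(omega)^2 + Var(omega) = (mp*expected_theta)^2.
    """
    if k_s < 1 or int(k_s) != k_s:
        raise InvalidParameterError("k_s must be a positive integer")
    if sigma2_YM <= 0:
        raise InvalidParameterError("sigma2_YM must be positive")
    if not abs(rho_gd) < 1:
        raise InvalidParameterError("|rho_gd| must be < 1")
    sigma2_d = sigma2_YM / k_s
    target = (mp * expected_theta) ** 2
    sigma2_g = target / (k_s * sigma2_d + (k_s**2 + k_s) * rho_gd**2 * sigma2_d)
    sigma_gd = rho_gd * math.sqrt(sigma2_g * sigma2_d)
    return sigma2_g, sigma2_d, sigma_gd


def draw_mediation_effects(k, p_k, sigma2_g, sigma2_d, sigma_gd, rng, k_s=None):
    """Spike-and-slab draw: first k_s mediators from the bivariate slab, rest 0."""
    if sigma2_g < 0 or sigma2_d < 0 or sigma_gd**2 > sigma2_g * sigma2_d + 1e-15:
        raise InvalidParameterError("slab covariance must be positive semi-definite")
    if k_s is None:
        k_s = int(round(p_k * k))
    gamma = np.zeros(k)
    delta = np.zeros(k)
    if k_s > 0:
        cov = np.array([[sigma2_g, sigma_gd], [sigma_gd, sigma2_d]])
        draws = rng.multivariate_normal(np.zeros(2), cov, size=k_s, method="svd")
        gamma[:k_s] = draws[:, 0]
        delta[:k_s] = draws[:, 1]
    return gamma, delta


def compute_direct_effect(mp, gamma, delta, expected_theta, rng, null_spread=0.5):
    """Direct effect consistent with the target MP.

    mp > 0: alpha = ((1-mp)/mp) * gamma'delta, so that 1 - alpha/theta = mp.
    mp == 0: alpha ~ Uniform((1-spread)E(theta), (1+spread)E(theta)).
    """
    if not 0 <= mp <= 1:
        raise InvalidParameterError("mp must lie in [0, 1]")
    if mp == 0:
        lo = (1 - null_spread) * expected_theta
        hi = (1 + null_spread) * expected_theta
        return float(rng.uniform(min(lo, hi), max(lo, hi)))
    omega = float(np.dot(gamma, delta))
    if omega == 0:
        raise DegenerateModelError("mp > 0 requires a non-zero indirect effect")
    return (1 - mp) / mp * omega


def draw_mediator_heritabilities(k, rng, shape=WEIBULL_SHAPE, scale=WEIBULL_SCALE):
    """i.i.d. Weibull(shape, scale) truncated to [0, 1], via the inverse CDF."""
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    cdf_at_1 = 1.0 - math.exp(-((1.0 / scale) ** shape))
    u = rng.uniform(0.0, cdf_at_1, size=k)
    return scale * (-np.log1p(-u)) ** (1.0 / shape)


def draw_instrument_counts(k, rng, mean=3.0):
    """Zero-truncated geometric counts of instruments per mediator."""
    if mean < 1:
        raise InvalidParameterError("mean instrument count must be >= 1")
    return rng.geometric(1.0 / mean, size=k)


def draw_instrument_effects(h2_X, m, h2_M, l_per_mediator, rng):
    """Gaussian instrument effects rescaled post hoc to exact heritabilities.

    beta ~ N(0, (h2_X/m) I_m) rescaled so sum(beta^2) == h2_X; mediator j's
    instrument block B[rows_j, j] ~ N(0, h2_Mj/l_j) rescaled so its sum of
    squares equals h2_Mj; B is zero outside the blocks.
    """
    if not 0 < h2_X < 1:
        raise InvalidParameterError("h2_X must lie in (0, 1)")
    h2_M = np.asarray(h2_M, dtype=float)
    l_per = np.asarray(l_per_mediator, dtype=int)
    if np.any(l_per < 1):
        raise InvalidParameterError("every mediator needs at least one instrument")
    if np.any(h2_M <= 0) or np.any(h2_M > 1):
        raise InvalidParameterError("mediator heritabilities must lie in (0, 1]")
    k = len(h2_M)
    beta = rng.normal(0.0, math.sqrt(h2_X / m), size=m)
    beta *= math.sqrt(h2_X / float(beta @ beta))
    l = int(l_per.sum())
    B = np.zeros((l, k))
    owner = np.empty(l, dtype=int)
    start = 0
    for j in range(k):
        stop = start + l_per[j]
        vals = rng.normal(0.0, math.sqrt(h2_M[j] / l_per[j]), size=l_per[j])
        vals *= math.sqrt(h2_M[j] / float(vals @ vals))
        B[start:stop, j] = vals
        owner[start:stop] = j
        start = stop
    return beta, B, owner


def make_sigma(strategy, k, rng, shrinkage=1e-6, corr=None):
    """Mediator phenotypic correlation matrix and its Cholesky factor.

    ``random_vectors`` correlates k standard-Gaussian 10-vectors, which for
    k comparable to or above 10 yields heavy sampling correlations and a
    rank-deficient matrix; shrinkage toward the identity restores positive
    definiteness.
    """
    if strategy == "identity":
        sigma = np.eye(k)
        return sigma, np.eye(k)
    if strategy == "random_vectors":
        v = rng.standard_normal((k, 10))
        sigma = np.corrcoef(v)
    elif strategy == "empirical_matrix":
        if corr is None:
            raise InvalidParameterError(
                "empirical_matrix requires a user-supplied correlation matrix")
        sigma = np.asarray(corr, dtype=float)
        if sigma.shape != (k, k) or not np.allclose(sigma, sigma.T):
            raise InvalidParameterError("correlation matrix must be symmetric k x k")
    else:
        raise InvalidParameterError(f"unknown Sigma strategy {strategy!r}")
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        sigma = (1.0 - shrinkage) * sigma + shrinkage * np.eye(k)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as err:
            raise InvalidParameterError(
                "Sigma not positive definite even after shrinkage; "
                "increase the shrinkage parameter") from err
    return sigma, chol


def simulate_summary_stats(truth: TrueEffects, arch: GeneticArchitecture,
                           scenario: Scenario, rng) -> SummaryData:
    """Noisy summary statistics given a ground-truth model.

    beta_hat ~ N(beta, I/n_X); rows of B_hat (C_hat) get noise with
    cross-mediator covariance Sigma/n_M ((1/n_M + sigma2_C) Sigma); c_hat and
    b_hat get homoscedastic outcome-study noise (1/n_Y plus pleiotropy).
    """
    m, k, l = arch.m, arch.k, arch.l
    L = arch.chol
    beta_hat = arch.beta + rng.standard_normal(m) / math.sqrt(scenario.n_X)
    B_hat = arch.B + (rng.standard_normal((l, k)) @ L.T) / math.sqrt(scenario.n_M)
    sd_C = math.sqrt(1.0 / scenario.n_M + scenario.sigma2_C)
    C_hat = np.outer(arch.beta, truth.gamma) + (rng.standard_normal((m, k)) @ L.T) * sd_C
    sd_c = math.sqrt(1.0 / scenario.n_Y + scenario.sigma2_c)
    c_hat = arch.beta * truth.theta + rng.standard_normal(m) * sd_c
    sd_b = math.sqrt(1.0 / scenario.n_Y + scenario.sigma2_b)
    b_hat = arch.B @ truth.delta + rng.standard_normal(l) * sd_b
    return SummaryData(
        beta_hat=beta_hat, C_hat=C_hat, B_hat=B_hat, c_hat=c_hat, b_hat=b_hat,
        n_X=scenario.n_X, n_M=scenario.n_M, n_Y=scenario.n_Y,
        sigma2_C=scenario.sigma2_C, sigma2_c=scenario.sigma2_c,
        sigma2_b=scenario.sigma2_b, owner=arch.owner.copy(),
    )


def mediator_ivw_pvalues(data: SummaryData) -> np.ndarray:
    """IVW MR p-value of the exposure -> mediator effect, per mediator."""
    btb = float(data.beta_hat @ data.beta_hat)
    if btb == 0:
        return np.ones(data.k)
    gamma_hat = data.beta_hat @ data.C_hat / btb
    var = data.var_C_element / btb
    return stats.chi2.sf(gamma_hat**2 / var, df=1)


def select_mediators(data: SummaryData, threshold: float) -> np.ndarray:
    """Indices of mediators whose exposure->mediator IVW p-value passes P."""
    if not 0 < threshold <= 1:
        raise InvalidParameterError("threshold must lie in (0, 1]")
    if threshold >= 1:
        return np.arange(data.k)
    return np.flatnonzero(mediator_ivw_pvalues(data) <= threshold)


def simulate_truth(scenario: Scenario, rng) -> tuple[TrueEffects, GeneticArchitecture]:
    """Ground-truth effects and genetic architecture for one replicate."""
    ks = scenario.k_s
    if ks >= 1:
        s2g, s2d, sgd = solve_prior_variances(
            scenario.mp, scenario.expected_theta, scenario.sigma2_YM,
            scenario.rho_gd, ks)
        gamma, delta = draw_mediation_effects(
            scenario.k, scenario.p_k, s2g, s2d, sgd, rng, k_s=ks)
    else:
        gamma = np.zeros(scenario.k)
        delta = np.zeros(scenario.k)
    alpha = compute_direct_effect(
        scenario.mp, gamma, delta, scenario.expected_theta, rng,
        null_spread=scenario.alpha_null_spread)
    truth = TrueEffects(alpha=alpha, gamma=gamma, delta=delta, mp=scenario.mp)
    truth.validate()
    h2_M = draw_mediator_heritabilities(scenario.k, rng)
    l_per = draw_instrument_counts(scenario.k, rng, mean=scenario.mean_instruments)
    beta, B, owner = draw_instrument_effects(
        scenario.h2_X, scenario.m, h2_M, l_per, rng)
    sigma, chol = make_sigma(scenario.sigma_strategy, scenario.k, rng)
    arch = GeneticArchitecture(beta=beta, B=B, h2_M=h2_M, l_per_mediator=l_per,
                               Sigma=sigma, chol=chol, owner=owner)
    return truth, arch


def simulate_replicate(scenario: Scenario, rng):
    """One full replicate: (truth, architecture, summary data)."""
    truth, arch = simulate_truth(scenario, rng)
    data = simulate_summary_stats(truth, arch, scenario, rng)
    return truth, arch, data


def simulate_selected_replicate(scenario: Scenario, rng, max_resim: int = 200):
    """Replicate plus IVW mediator selection, re-simulating on empty sets.

    Returns (truth, arch, selected data, selected indices, n_resimulations).
    Re-simulation on an empty selection reproduces the study procedure and can
    introduce mild winner's curse; the count is reported for transparency.
    """
    threshold = scenario.selection_threshold
    for attempt in range(max_resim + 1):
        truth, arch, data = simulate_replicate(scenario, rng)
        idx = select_mediators(data, threshold)
        if idx.size > 0:
            return truth, arch, data.subset(idx), idx, attempt
    raise RuntimeError(
        f"no mediators selected after {max_resim} re-simulations; "
        "the selection threshold is likely too strict for this scenario")
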