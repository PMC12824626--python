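import numpy as np
import pytest

from lima.data import Scenario
from lima.synth import simulate_replicate, simulate_truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_scenario():
    """Desk-scale scenario used for unit tests (fast, still well-conditioned)."""
    return Scenario(m=20, k=3, p_k=1.0, n_X=50_000, n_M=5_000, n_Y=50_000,
                    sigma2_YM=0.03, seed=0)


@pytest.fixture
def small_replicate(small_scenario):
    rng = np.random.default_rng(np.random.SeedSequence(123))
    return simulate_replicate(small_scenario, rng)


def noiseless_data(truth, arch, scenario):
    """Summary statistics at the infinite-sample limit (estimates == truth)."""
    from lima.data import SummaryData

    return SummaryData(
        beta_hat=arch.beta.copy(),
        C_hat=np.outer(arch.beta, truth.gamma),
        B_hat=arch.B.copy(),
        c_hat=arch.beta * truth.theta,
        b_hat=arch.B @ truth.delta,
        n_X=scenario.n_X, n_M=scenario.n_M, n_Y=scenario.n_Y,
        owner=arch.owner.copy(),
    )


@pytest.fixture
def small_noiseless(small_scenario):
    """Noiseless data with strongly instrumented mediators.

    Heritabilities are fixed (not Weibull-drawn) so every mediator is well
    identified: exact parameter recovery is only guaranteed away from the
    weak-instrument regime, where the likelihood's variance terms reward
    shrinking poorly identified effects.
    """
    import lima.synth as synth
    from lima.data import GeneticArchitecture, TrueEffects

    rng = np.random.default_rng(np.random.SeedSequence(7))
    sc = small_scenario
    s2g, s2d, sgd = synth.solve_prior_variances(
        sc.mp, sc.expected_theta, sc.sigma2_YM, sc.rho_gd, sc.k_s)
    gamma, delta = synth.draw_mediation_effects(
        sc.k, sc.p_k, s2g, s2d, sgd, rng, k_s=sc.k_s)
    alpha = synth.compute_direct_effect(sc.mp, gamma, delta,
                                        sc.expected_theta, rng)
    truth = TrueEffects(alpha=alpha, gamma=gamma, delta=delta, mp=sc.mp)
    h2_M = np.array([0.12, 0.2, 0.08])
    l_per = np.array([2, 1, 2])
    beta, B, owner = synth.draw_instrument_effects(sc.h2_X, sc.m, h2_M,
                                                   l_per, rng)
    arch = GeneticArchitecture(beta=beta, B=B, h2_M=h2_M,
                               l_per_mediator=l_per, Sigma=np.eye(sc.k),
                               chol=np.eye(sc.k), owner=owner)
    big_n = sc.with_(n_X=10**9, n_M=10**9, n_Y=10**9)
    return truth, arch, noiseless_data(truth, arch, big_n)
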