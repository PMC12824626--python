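"""Generative-model tests: prior solving, spike-and-slab draws, architecture,
noise distributions, mediator selection, determinism, serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from lima.data import (DegenerateModelError, InvalidParameterError, Scenario,
                       SummaryData)
from lima import synth
from lima.synth import (compute_direct_effect, draw_instrument_effects,
                        draw_mediation_effects, draw_mediator_heritabilities,
                        make_sigma, select_mediators, simulate_replicate,
                        simulate_truth, solve_prior_variances)


class TestPriorVariances:
    def test_hand_worked_example(self):
        s2g, s2d, sgd = solve_prior_variances(
            mp=0.15, expected_theta=0.15, sigma2_YM=0.01, rho_gd=0.0, k_s=1)
        assert s2d == pytest.approx(0.01)
        assert s2g == pytest.approx(0.0225**2 / 0.01)
        assert sgd == 0.0

    def test_zero_mediation_forces_zero_covariance(self):
        s2g, s2d, sgd = solve_prior_variances(0.0, 0.2, 0.05, 0.7, 5)
        assert sgd == 0.0 and s2g == 0.0
        assert 5 * sgd == 0.0  # E(omega) = k_s * sigma_gd

    @given(mp=st.floats(0.01, 1.0), et=st.floats(0.01, 0.5),
           s2ym=st.floats(1e-4, 0.5), rho=st.floats(-0.95, 0.95),
           ks=st.integers(1, 50))
    @settings(max_examples=200, deadline=None)
    def test_second_moment_identity(self, mp, et, s2ym, rho, ks):
        """E(omega)^2 + Var(omega) equals the squared target indirect effect."""
        s2g, s2d, sgd = solve_prior_variances(mp, et, s2ym, rho, ks)
        second_moment = ks * (s2g * s2d + sgd**2) + (ks * sgd) ** 2
        assert second_moment == pytest.approx((mp * et) ** 2, rel=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            solve_prior_variances(0.1, 0.1, 0.0, 0.0, 1)
        with pytest.raises(InvalidParameterError):
            solve_prior_variances(0.1, 0.1, 0.1, 0.0, 0)
        with pytest.raises(InvalidParameterError):
            solve_prior_variances(0.1, 0.1, 0.1, 1.0, 2)


class TestMediationEffects:
    def test_spike_structure(self, rng):
        gamma, delta = draw_mediation_effects(10, 0.3, 0.01, 0.02, 0.005, rng)
        assert np.all(gamma[3:] == 0) and np.all(delta[3:] == 0)
        assert np.all(gamma[:3] != 0) and np.all(delta[:3] != 0)

    def test_zero_pk_gives_all_zero(self, rng):
        gamma, delta = draw_mediation_effects(5, 0.0, 0.01, 0.02, 0.0, rng)
        assert np.all(gamma == 0) and np.all(delta == 0)

    def test_slab_moments_match_prior(self, rng):
        """LLN checks of E(gamma_i delta_i) and Var(gamma'delta)."""
        s2g, s2d, sgd = 0.01, 0.02, 0.007
        n, ks = 100_000, 4
        prods = np.empty(n)
        omegas = np.empty(n)
        cov = np.array([[s2g, sgd], [sgd, s2d]])
        draws = rng.multivariate_normal(np.zeros(2), cov, size=(n, ks))
        prods = (draws[:, :, 0] * draws[:, :, 1])[:, 0]
        omegas = np.einsum("nk,nk->n", draws[:, :, 0], draws[:, :, 1])
        se_mean = prods.std() / math.sqrt(n)
        assert abs(prods.mean() - sgd) < 4 * se_mean
        var_target = ks * (s2g * s2d + sgd**2)
        se_var = omegas.var() * math.sqrt(2.0 / n)  # rough chi2-based SE
        assert abs(omegas.var() - var_target) < 6 * se_var

    def test_indefinite_covariance_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            draw_mediation_effects(3, 1.0, 0.01, 0.01, 0.02, rng)


class TestDirectEffect:
    def test_hand_examples(self, rng):
        assert compute_direct_effect(0.5, np.array([0.5]), np.array([0.2]),
                                     0.1, rng) == pytest.approx(0.1)
        alpha = compute_direct_effect(0.15, np.array([0.15]), np.array([0.15]),
                                      0.15, rng)
        theta = alpha + 0.15 * 0.15
        assert alpha == pytest.approx(0.1275)
        assert 1 - alpha / theta == pytest.approx(0.15)

    def test_null_model_uniform_around_expected_theta(self, rng):
        draws = [compute_direct_effect(0.0, np.zeros(1), np.zeros(1), 0.15, rng)
                 for _ in range(4000)]
        draws = np.asarray(draws)
        assert np.all((draws >= 0.075) & (draws <= 0.225))
        assert abs(draws.mean() - 0.15) < 4 * draws.std() / math.sqrt(draws.size)

    def test_degenerate_model(self, rng):
        with pytest.raises(DegenerateModelError):
            compute_direct_effect(0.3, np.zeros(2), np.zeros(2), 0.15, rng)


class TestHeritabilities:
    def test_truncation_and_quadrature_mean(self, rng):
        h2 = draw_mediator_heritabilities(200_000, rng)
        assert np.all((h2 >= 0) & (h2 <= 1))
        shape, scale = 0.5, 0.05
        norm = stats.weibull_min.cdf(1.0, shape, scale=scale)
        mean_true, _ = integrate.quad(
            lambda x: x * stats.weibull_min.pdf(x, shape, scale=scale) / norm,
            0, 1)
        se = h2.std() / math.sqrt(h2.size)
        assert abs(h2.mean() - mean_true) < 4 * se

    def test_cdf_at_005(self, rng):
        h2 = draw_mediator_heritabilities(200_000, rng)
        shape, scale = 0.5, 0.05
        cdf_true = (stats.weibull_min.cdf(0.05, shape, scale=scale)
                    / stats.weibull_min.cdf(1.0, shape, scale=scale))
        emp = np.mean(h2 <= 0.05)
        se = math.sqrt(cdf_true * (1 - cdf_true) / h2.size)
        assert abs(emp - cdf_true) < 3 * se


class TestInstrumentEffects:
    def test_exact_heritability_scaling_and_blocks(self, rng):
        h2_M = np.array([0.1, 0.3, 0.05])
        l_per = np.array([2, 3, 1])
        beta, B, owner = draw_instrument_effects(0.35, 10, h2_M, l_per, rng)
        assert beta @ beta == pytest.approx(0.35, abs=1e-14)
        for j, (start, stop) in enumerate([(0, 2), (2, 5), (5, 6)]):
            col = B[:, j]
            assert np.all(col[start:stop] != 0)
            mask = np.ones(6, bool); mask[start:stop] = False
            assert np.all(col[mask] == 0)
            assert col @ col == pytest.approx(h2_M[j], abs=1e-14)
        assert list(owner) == [0, 0, 1, 1, 1, 2]

    def test_two_singleton_mediators_give_diagonal(self, rng):
        _, B, _ = draw_instrument_effects(0.2, 5, [0.1, 0.2], [1, 1], rng)
        assert B.shape == (2, 2)
        assert B[0, 1] == 0 and B[1, 0] == 0 and B[0, 0] != 0 and B[1, 1] != 0


class TestSigma:
    def test_identity(self, rng):
        sigma, chol = make_sigma("identity", 4, rng)
        assert np.array_equal(sigma, np.eye(4))

    def test_random_vectors_heavy_correlation_and_pd(self, rng):
        sigma, chol = make_sigma("random_vectors", 50, rng)
        off = sigma[~np.eye(50, dtype=bool)]
        # 10-dimensional vectors induce strong sampling correlation
        assert np.mean(np.abs(off)) > 0.15
        assert np.allclose(chol @ chol.T, sigma, atol=1e-8)
        assert np.all(np.linalg.eigvalsh(sigma) > 0)

    def test_empirical_requires_matrix(self, rng):
        with pytest.raises(InvalidParameterError):
            make_sigma("empirical_matrix", 3, rng)
        corr = np.array([[1, 0.4, 0], [0.4, 1, 0.1], [0, 0.1, 1.0]])
        sigma, chol = make_sigma("empirical_matrix", 3, rng, corr=corr)
        assert np.allclose(chol @ chol.T, sigma)


class TestSummaryNoise:
    def test_noiseless_limit_exact(self, small_noiseless):
        truth, arch, data = small_noiseless
        assert np.array_equal(data.beta_hat, arch.beta)
        assert np.allclose(data.C_hat, np.outer(arch.beta, truth.gamma))
        assert np.allclose(data.c_hat, arch.beta * truth.theta)
        assert np.allclose(data.b_hat, arch.B @ truth.delta)

    def test_noise_distributions(self):
        """Goodness of fit of the five noise models over many replicates."""
        sc = Scenario(m=6, k=3, p_k=1.0, n_X=5_000, n_M=2_000, n_Y=8_000,
                      sigma2_YM=0.03, sigma_strategy="random_vectors",
                      sigma2_C=1e-4, seed=0)
        rng = np.random.default_rng(99)
        truth, arch = simulate_truth(sc, rng)
        n = 2000
        zc, zb, zC_rows, zB_rows = [], [], [], []
        L_inv = np.linalg.inv(arch.chol)
        for _ in range(n):
            d = synth.simulate_summary_stats(truth, arch, sc, rng)
            zc.append((d.c_hat - arch.beta * truth.theta)
                      / math.sqrt(1 / sc.n_Y))
            zb.append((d.b_hat - arch.B @ truth.delta) / math.sqrt(1 / sc.n_Y))
            rows_C = (d.C_hat - np.outer(arch.beta, truth.gamma))
            zC_rows.append(rows_C @ L_inv.T / math.sqrt(1 / sc.n_M + sc.sigma2_C))
            zB_rows.append((d.B_hat - arch.B) @ L_inv.T / math.sqrt(1 / sc.n_M))
        for z in (zc, zb, zC_rows, zB_rows):
            flat = np.concatenate([np.ravel(x) for x in z])
            assert stats.kstest(flat, "norm").pvalue > 0.01
        # row covariance of C_hat noise matches the target matrix
        mean_C = np.outer(arch.beta, truth.gamma)
        rows = np.array([
            (synth.simulate_summary_stats(truth, arch, sc, rng).C_hat - mean_C)[0]
            for _ in range(4000)])
        emp = np.cov(rows.T)
        target = (1 / sc.n_M + sc.sigma2_C) * arch.Sigma
        assert np.allclose(emp, target, atol=4 * target[0, 0] / math.sqrt(4000) * 3)

    def test_c_hat_variance(self):
        sc = Scenario(m=4, k=2, p_k=1.0, n_X=5_000, n_M=5_000, n_Y=1_000,
                      sigma2_c=2e-4, seed=0)
        rng = np.random.default_rng(11)
        truth, arch = simulate_truth(sc, rng)
        resid = np.array([synth.simulate_summary_stats(truth, arch, sc, rng).c_hat
                          - arch.beta * truth.theta for _ in range(5000)])
        target = 1 / sc.n_Y + sc.sigma2_c
        emp = resid.var()
        assert emp == pytest.approx(target, rel=0.1)


class TestSelection:
    def test_threshold_one_keeps_all(self, small_replicate):
        _, _, data = small_replicate
        assert list(select_mediators(data, 1.0)) == list(range(data.k))

    def test_null_mediator_selection_size(self):
        """A gamma=0 mediator is kept with probability ~ the threshold."""
        sc = Scenario(m=20, k=1, p_k=1.0, mp=0.0, n_X=50_000, n_M=5_000,
                      n_Y=50_000, seed=0)
        rng = np.random.default_rng(21)
        threshold = 0.05
        kept = 0
        n = 3000
        for _ in range(n):
            truth, arch, data = simulate_replicate(sc, rng)
            kept += select_mediators(data, threshold).size
        rate = kept / n
        se = math.sqrt(threshold * (1 - threshold) / n)
        assert abs(rate - threshold) < 4 * se

    def test_subset_restricts_blocks(self, small_replicate):
        _, arch, data = small_replicate
        sub = data.subset([1])
        assert sub.k == 1
        assert sub.l == int(arch.l_per_mediator[1])
        assert np.array_equal(sub.owner, np.zeros(sub.l, dtype=int))
        rows = arch.owner == 1
        assert np.array_equal(sub.b_hat, data.b_hat[rows])


class TestReproducibility:
    def test_bit_identical_replicates(self, small_scenario):
        r1 = simulate_replicate(small_scenario,
                                np.random.default_rng(np.random.SeedSequence(5)))
        r2 = simulate_replicate(small_scenario,
                                np.random.default_rng(np.random.SeedSequence(5)))
        for a, b in [(r1[2].beta_hat, r2[2].beta_hat), (r1[2].C_hat, r2[2].C_hat),
                     (r1[2].B_hat, r2[2].B_hat), (r1[2].c_hat, r2[2].c_hat),
                     (r1[2].b_hat, r2[2].b_hat)]:
            assert np.array_equal(a, b)

    def test_tsv_roundtrip(self, small_replicate, tmp_path):
        _, _, data = small_replicate
        data.to_dir(tmp_path / "model", meta={"seed": 123})
        back = SummaryData.from_dir(tmp_path / "model")
        assert np.allclose(back.beta_hat, data.beta_hat)
        assert np.allclose(back.C_hat, data.C_hat)
        assert np.allclose(back.B_hat, data.B_hat)
        assert np.allclose(back.var_b, data.var_b)
        assert np.array_equal(back.owner, data.owner)
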