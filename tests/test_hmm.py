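"""HMM algorithms against independent oracles: scipy densities, path
enumeration, and direct single-distribution maximum likelihood."""
import numpy as np
import pytest
from scipy import integrate, optimize, stats

import movescape as ms
from movescape.hmm import (
    DecodedBurst,
    aic,
    angle_emission,
    build_start_grid,
    count_free_params,
    plausibility_check,
    predictive_power,
    step_emission,
)
from movescape.tracks import StepSeries

from _oracles import enum_loglik, enum_posteriors, enum_viterbi, random_hmm_case
from conftest import SUBURBAN_2STATE, regime_config


class TestStepEmission:
    def test_zero_step_returns_point_mass(self):
        assert step_emission(0.0, 100.0, 50.0, z=0.1) == 0.1

    def test_no_inflation_reduces_to_gamma_density(self):
        L = np.array([0.5, 7.6, 50.0, 300.0])
        ours = step_emission(L, 7.6, 7.2, z=0.0)
        oracle = stats.gamma.pdf(L, 7.6**2 / 7.2**2, scale=7.2**2 / 7.6)
        np.testing.assert_allclose(ours, oracle, rtol=1e-12)

    def test_mean_sd_parameterization_and_quadrature_oracle(self):
        # mean 7.6 m, SD 7.2 m: shape ~= 1.114, scale ~= 6.821
        mean, sd = 7.6, 7.2
        assert mean**2 / sd**2 == pytest.approx(1.114, abs=5e-4)
        assert sd**2 / mean == pytest.approx(6.821, abs=5e-4)
        dens = step_emission(7.6, mean, sd, z=0.0)
        # independent check: density integrates to 1 and matches quadrature
        # of the same normalized integrand at the evaluation point
        integrand = lambda u: u ** (mean**2 / sd**2 - 1) * np.exp(-u * mean / sd**2)
        norm, _ = integrate.quad(integrand, 0, np.inf)
        assert dens == pytest.approx(integrand(7.6) / norm, rel=1e-8)

    def test_zero_inflation_renormalizes_continuous_part(self):
        total, _ = integrate.quad(
            lambda u: step_emission(u, 100.0, 60.0, z=0.25), 0, np.inf
        )
        assert total == pytest.approx(0.75, rel=1e-8)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            step_emission(-1.0, 10.0, 10.0)


class TestAngleEmission:
    def test_zero_concentration_is_circular_uniform(self):
        for phi in (-3.0, 0.0, 2.5):
            assert angle_emission(phi, 1.0, 0.0) == pytest.approx(1 / (2 * np.pi))

    def test_density_at_mean_matches_bessel_series(self):
        # I0(2) by power series: sum (x^2/4)^k / (k!)^2
        import math

        i0 = sum((2.0**2 / 4) ** k / math.factorial(k) ** 2 for k in range(40))
        expected = np.exp(2.0) / (2 * np.pi * i0)
        assert expected == pytest.approx(0.5159, abs=1e-4)
        assert angle_emission(0.7, 0.7, 2.0) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("kappa", [0.0, 1.0, 5.0])
    def test_density_integrates_to_one(self, kappa):
        total, _ = integrate.quad(
            lambda p: angle_emission(p, 0.4, kappa), -np.pi, np.pi
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_missing_angle_contributes_factor_one(self):
        assert angle_emission(np.nan, 0.0, 3.0) == 1.0


class TestForwardAgainstEnumeration:
    def test_small_chain_matches_path_enumeration(self):
        rng = np.random.default_rng(12)
        series, params = random_hmm_case(rng, T=6, K=2)
        ours = ms.forward_loglik([series], params)
        assert ours == pytest.approx(enum_loglik(series, params), abs=1e-8)

    def test_one_state_is_sum_of_log_densities(self):
        rng = np.random.default_rng(3)
        series, params = random_hmm_case(rng, T=30, K=1)
        direct = np.sum(
            np.log(
                step_emission(
                    series.lengths, params.step_means[0], params.step_sds[0],
                    params.zero_mass[0],
                )
                * angle_emission(series.angles, params.angle_means[0], params.kappas[0])
            )
        )
        assert ms.forward_loglik([series], params) == pytest.approx(direct, abs=1e-9)

    def test_frozen_chain_equals_single_state_loglik(self):
        rng = np.random.default_rng(4)
        series, params = random_hmm_case(rng, T=20, K=2)
        frozen = ms.HMMParams(
            params.step_means, params.step_sds, params.zero_mass,
            params.angle_means, params.kappas, np.eye(2),
        )
        ll = ms.forward_loglik([series], frozen, delta=[1.0, 0.0])
        one = ms.HMMParams(
            params.step_means[:1], params.step_sds[:1], params.zero_mass[:1],
            params.angle_means[:1], params.kappas[:1], [[1.0]],
        )
        assert ll == pytest.approx(ms.forward_loglik([series], one), abs=1e-9)

    def test_loglik_invariant_under_burst_permutation(self):
        rng = np.random.default_rng(5)
        s1, params = random_hmm_case(rng, T=40, K=3)
        s2, _ = random_hmm_case(rng, T=25, K=3)
        assert ms.forward_loglik([s1, s2], params) == pytest.approx(
            ms.forward_loglik([s2, s1], params), abs=1e-10
        )

    def test_impossible_observation_reports_step_index(self):
        series = StepSeries([10.0, 0.0, 20.0], [np.nan, np.nan, np.nan], "b1")
        params = ms.HMMParams([10.0], [5.0], [0.0], [0.0], [1.0], [[1.0]])
        with pytest.raises(ValueError, match="step 1"):
            ms.forward_loglik([series], params)


class TestViterbiAndPosteriors:
    def test_one_state_decodes_constant(self):
        rng = np.random.default_rng(6)
        series, params = random_hmm_case(rng, T=15, K=1)
        assert np.all(ms.viterbi(series, params) == 1)
        np.testing.assert_allclose(ms.state_posteriors(series, params), 1.0)

    def test_viterbi_matches_enumeration_k3(self):
        rng = np.random.default_rng(7)
        series, params = random_hmm_case(rng, T=8, K=3)
        np.testing.assert_array_equal(
            ms.viterbi(series, params), enum_viterbi(series, params)
        )

    def test_viterbi_ties_break_to_lower_state(self):
        # identical emissions in both states and a symmetric chain: every
        # path has equal likelihood, so the decoder must return all ones
        series = StepSeries([50.0, 60.0, 70.0], [np.nan, 0.2, -0.4], "tie")
        params = ms.HMMParams(
            [100.0, 100.0], [50.0, 50.0], [0.0, 0.0], [0.0, 0.0], [1.0, 1.0],
            [[0.5, 0.5], [0.5, 0.5]],
        )
        assert np.all(ms.viterbi(series, params) == 1)

    def test_posteriors_match_enumeration(self):
        rng = np.random.default_rng(8)
        series, params = random_hmm_case(rng, T=6, K=2)
        np.testing.assert_allclose(
            ms.state_posteriors(series, params),
            enum_posteriors(series, params),
            atol=1e-8,
        )

    def test_confident_posteriors_agree_with_viterbi(self, suburban_series_5000):
        series, track = suburban_series_5000
        cfg = regime_config(SUBURBAN_2STATE, 1, seed=1)
        params = ms.HMMParams(
            cfg.step_means, cfg.step_sds, cfg.zero_mass, cfg.angle_means,
            cfg.kappas, cfg.tmat,
        )
        post = ms.state_posteriors(series, params)
        vit = ms.viterbi(series, params)
        confident = post.max(axis=1) > 0.75
        assert np.mean(post.argmax(axis=1)[confident] + 1 == vit[confident]) > 0.99
        # decoding recovers the known states on well-separated regimes
        assert np.mean(vit - 1 == track.true_states) >= 0.95


class TestPredictivePower:
    def _decoded(self, rows):
        rows = np.asarray(rows, float)
        return DecodedBurst("b", rows.argmax(axis=1) + 1, rows)

    def test_certain_rows_score_one(self):
        index, strong = predictive_power([self._decoded([[1, 0]] * 4)])
        assert index == 1.0 and strong

    def test_coin_flip_rows_not_strong(self):
        index, strong = predictive_power([self._decoded([[0.5, 0.5]] * 4)])
        assert index == 0.5 and not strong

    def test_boundary_090_is_inclusive(self):
        d = self._decoded([[1, 0], [1, 0], [0.8, 0.2], [0.2, 0.8]])
        index, strong = predictive_power([d])
        assert index == pytest.approx(0.9) and strong

    def test_invariant_under_state_relabeling(self):
        rng = np.random.default_rng(9)
        rows = rng.dirichlet(np.ones(3), size=20)
        a = predictive_power([self._decoded(rows)])
        b = predictive_power([self._decoded(rows[:, ::-1])])
        assert a == b


class TestModelSize:
    def test_aic_arithmetic(self):
        assert aic(-1000.0, 12) == 2024.0

    @pytest.mark.parametrize("K,zeros,expected", [(2, True, 12), (3, True, 21),
                                                  (2, False, 10), (1, True, 5)])
    def test_free_parameter_count(self, K, zeros, expected):
        assert count_free_params(K, zeros) == expected


class TestPlausibility:
    def _params(self, means, kappas=None):
        K = len(means)
        kappas = kappas if kappas is not None else np.linspace(0.5, 2.0, K)
        tmat = np.full((K, K), 0.1 / max(K - 1, 1))
        np.fill_diagonal(tmat, 0.9 if K > 1 else 1.0)
        return ms.HMMParams(means, np.asarray(means) * 0.8, [0.01] * K,
                            [0.0] * K, kappas, tmat)

    def test_three_distinct_states_labeled(self):
        report = plausibility_check(self._params([7.5, 122.0, 625.0]))
        assert report.plausible
        assert report.labels == ("encamped", "foraging", "traveling")

    def test_indistinct_means_fail(self):
        report = plausibility_check(self._params([100.0, 102.0, 625.0]))
        assert not report.plausible
        assert any("indistinct" in r for r in report.reasons)

    def test_two_state_labels(self):
        report = plausibility_check(self._params([7.6, 319.0]))
        assert report.plausible and report.labels == ("encamped", "moving")

    def test_traveling_must_be_most_directed_moving_state(self):
        report = plausibility_check(
            self._params([7.5, 122.0, 625.0], kappas=[0.5, 2.0, 0.7])
        )
        assert not report.plausible
        assert any("concentration" in r for r in report.reasons)

    def test_labels_follow_mean_order_not_state_order(self):
        report = plausibility_check(self._params([319.0, 7.6][::-1]))
        assert report.labels == ("encamped", "moving")


class TestStationaryDistribution:
    def test_symmetric_chain_is_half_half(self):
        np.testing.assert_allclose(
            ms.stationary_distribution([[0.9, 0.1], [0.1, 0.9]]), [0.5, 0.5]
        )

    def test_asymmetric_chain_solves_linear_system(self):
        np.testing.assert_allclose(
            ms.stationary_distribution([[0.8, 0.2], [0.3, 0.7]]), [0.6, 0.4],
            atol=1e-12,
        )

    def test_identity_has_no_unique_solution(self):
        with pytest.raises(ValueError):
            ms.stationary_distribution(np.eye(2))


class TestStartGrid:
    def _series(self):
        rng = np.random.default_rng(10)
        L = rng.gamma(1.0, 100.0, 300)
        L[rng.random(300) < 0.1] = 0.0
        ang = rng.uniform(-np.pi, np.pi, 300)
        ang[0] = np.nan
        return StepSeries(L, ang, "g")

    def test_grid_size_is_product_of_candidate_sets(self):
        grid = build_start_grid(
            self._series(), 2,
            mean_quantile_sets=[[0.3, 0.6], [0.1, 0.9]],
            angle_candidates=(0.0, np.pi), kappa_candidates=(0.5, 2.0),
        )
        assert len(grid) == 2 * 2 * 2

    def test_starts_are_valid_and_sorted(self):
        for start in build_start_grid(self._series(), 3):
            assert np.all(np.diff(start.step_means) >= 0)
            assert np.all(start.tmat.sum(axis=1) == pytest.approx(1.0))
            assert np.all(start.zero_mass > 0)  # data contain zeros


class TestFitting:
    def test_one_state_matches_direct_mle(self):
        rng = np.random.default_rng(14)
        L = rng.gamma(2.0, 60.0, 400)
        L[rng.random(400) < 0.1] = 0.0
        ang = rng.vonmises(0.5, 1.2, 400)
        ang[0] = np.nan
        ang[L == 0] = np.nan
        series = StepSeries(L, ang, "mle")
        res = ms.fit_hmm([series], 1, warn_small=False)

        # independent single-distribution ML fit via scipy on its own
        # parameterization (log shape, log scale, logit z, mu, log kappa)
        pos, nz = L[L > 0], np.mean(L == 0)
        va = ang[~np.isnan(ang)]

        def nll(theta):
            sh, sc, kap = np.exp(theta[0]), np.exp(theta[1]), np.exp(theta[4])
            z = 1 / (1 + np.exp(-theta[2]))
            ll = (
                np.log(z) * np.sum(L == 0)
                + np.sum(np.log1p(-z) + stats.gamma.logpdf(pos, sh, scale=sc))
                + np.sum(stats.vonmises.logpdf(va, kap, loc=theta[3]))
            )
            return -ll

        x0 = [np.log(2.0), np.log(60.0), 0.0, 0.0, 0.0]
        direct = optimize.minimize(nll, x0, method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12,
                                            "maxiter": 20000})
        assert res.llf == pytest.approx(-direct.fun, abs=1e-6)

    def test_best_start_attains_maximum(self, suburban_fit_2state):
        lls = [l for l in suburban_fit_2state.start_logliks if l is not None]
        assert suburban_fit_2state.llf >= max(lls) - 1e-6

    def test_parameter_recovery_two_states(self):
        cfg = regime_config(SUBURBAN_2STATE, 3000, seed=21)
        track = ms.simulate_hmm_track(cfg)
        series = ms.steps_and_angles(track)
        res = ms.fit_hmm([series], 2)
        p, _ = res.sorted_params()
        np.testing.assert_allclose(p.step_means, cfg.step_means, rtol=0.10)
        np.testing.assert_allclose(p.step_sds, cfg.step_sds, rtol=0.15)
        np.testing.assert_allclose(
            np.diag(p.tmat), np.diag(cfg.tmat), rtol=0.10
        )
        vit = ms.viterbi(series, res.params)
        order = np.argsort(res.params.step_means)
        relabel = np.empty(2, int)
        relabel[order] = np.arange(2)
        assert np.mean(relabel[vit - 1] == track.true_states) >= 0.9

    def test_results_serialization_roundtrip(self, suburban_fit_2state, tmp_path):
        suburban_fit_2state.save(tmp_path / "fit.json")
        import json

        doc = json.loads((tmp_path / "fit.json").read_text())
        back = ms.HMMParams.from_dict(doc["params"])
        np.testing.assert_allclose(back.step_means,
                                   suburban_fit_2state.params.step_means)
        assert doc["aic"] == pytest.approx(suburban_fit_2state.aic)
        assert len(doc["starts"]) == 8

    def test_summary_mentions_labels_and_fit_stats(self, suburban_fit_2state):
        text = suburban_fit_2state.summary()
        assert "encamped" in text and "AIC" in text

    def test_state_density_plot_draws_one_curve_per_state(self, suburban_fit_2state):
        import matplotlib

        matplotlib.use("Agg", force=True)
        ax = suburban_fit_2state.plot_state_densities()
        assert len(ax.lines) == suburban_fit_2state.n_states
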