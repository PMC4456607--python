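import numpy as np
import pandas as pd
import pytest

import unzipmap as um


class TestPositionHistogram:
    def test_identical_positions_fill_single_bin(self):
        counts, edges = um.position_histogram([0.0] * 7, bin_bp=5.0)
        assert counts.sum() == 7
        assert counts.max() == 7
        filled = np.flatnonzero(counts)[0]
        assert edges[filled] < 0 < edges[filled + 1]

    def test_bin_centering_convention(self):
        counts, edges = um.position_histogram([-2.0, 2.0], bin_bp=5.0)
        assert counts.max() == 2  # both fall in the [-2.5, 2.5) bin

    def test_empty_input(self):
        counts, edges = um.position_histogram([], bin_bp=5.0)
        assert counts.size == 0


class TestPoissonEventFractions:
    def test_printed_once_multiple_split(self):
        ev = um.poisson_event_fractions(0.55)
        assert round(100 * ev.frac_once) == 73
        assert round(100 * ev.frac_multi) == 27
        assert ev.lam == pytest.approx(-np.log(0.55))

    def test_against_conditional_monte_carlo(self):
        for p0 in (0.3, 0.55, 0.8):
            ev = um.poisson_event_fractions(p0)
            rng = np.random.default_rng(12345)
            k = rng.poisson(ev.lam, size=10 ** 6)
            k = k[k >= 1]
            assert abs((k == 1).mean() - ev.frac_once) < 0.003

    def test_small_lambda_limit(self):
        assert um.poisson_event_fractions(0.9999).frac_once > 0.9999

    @pytest.mark.parametrize("p0", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_p0_rejected(self, p0):
        with pytest.raises(ValueError):
            um.poisson_event_fractions(p0)


class TestDoubleGaussianMixture:
    @staticmethod
    def _sample(w, n, seed, sd_narrow=2.0, sd_broad=30.0):
        rng = np.random.default_rng(seed)
        narrow = rng.random(n) < w
        x = np.where(narrow, rng.normal(0.0, sd_narrow, n),
                     rng.normal(0.0, sd_broad, n))
        return x

    @pytest.mark.parametrize("w", [0.3, 0.5, 0.56, 0.7])
    def test_weight_recovery(self, w):
        x = self._sample(w, 2000, seed=int(w * 100))
        fit = um.fit_double_gaussian(x)
        se = np.sqrt(w * (1 - w) / 2000)
        assert fit.converged
        assert fit.sigma1 <= fit.sigma2
        assert abs(fit.w_unremodeled - w) <= 3 * se + 0.01

    def test_mle_and_histogram_modes_agree(self):
        x = self._sample(0.56, 2000, seed=7)
        mle = um.fit_double_gaussian(x, mode="mle")
        hist = um.fit_double_gaussian(x, mode="hist")
        assert abs(mle.w_unremodeled - hist.w_unremodeled) <= 0.05

    def test_single_component_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        fit = um.fit_double_gaussian(rng.normal(0.0, 2.0, 500))
        assert fit.degenerate
        assert fit.w_unremodeled == 1.0

    def test_matches_sklearn_em_cross_check(self):
        from sklearn.mixture import GaussianMixture

        x = self._sample(0.56, 2000, seed=11)
        ours = um.DoubleGaussianMixture().fit(x)
        ref = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8,
                              max_iter=1000).fit(x.reshape(-1, 1))
        narrow = int(np.argmin(ref.covariances_.ravel()))
        assert ours.weight_narrow_ == pytest.approx(
            ref.weights_[narrow], abs=0.02)
        assert ours.sigmas_[0] == pytest.approx(
            float(np.sqrt(ref.covariances_.ravel()[narrow])), rel=0.1)

    def test_posterior_classification(self):
        x = self._sample(0.5, 2000, seed=3)
        est = um.DoubleGaussianMixture().fit(x)
        labels = est.predict([0.0, 100.0])
        assert labels[0] == 0 and labels[1] == 1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            um.fit_double_gaussian(np.zeros(10))


class TestBindingIsotherm:
    CONCS = np.array([0.5, 1.0, 2.0, 3.4, 5.0, 10.0, 20.0, 50.0])

    def test_noiseless_fit_is_exact(self):
        fractions = um.isotherm(self.CONCS, 3.4)
        est = um.BindingIsotherm().fit(self.CONCS, fractions)
        assert est.kd_ == pytest.approx(3.4, abs=1e-6)

    def test_unidentifiable_data_rejected(self):
        with pytest.raises(ValueError):
            um.BindingIsotherm().fit(self.CONCS, np.ones_like(self.CONCS))
        with pytest.raises(ValueError):
            um.BindingIsotherm().fit(self.CONCS, np.zeros_like(self.CONCS))

    def test_noisy_recovery_within_5pct(self):
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            f = um.isotherm(self.CONCS, 3.4) * rng.normal(1.0, 0.02, 8)
            est = um.BindingIsotherm().fit(self.CONCS, np.clip(f, 0, 1))
            errors.append(abs(est.kd_ - 3.4) / 3.4)
        assert np.median(errors) <= 0.05

    def test_titration_dataset_fit(self):
        ds = um.simulate_binding_titration(self.CONCS, 3.4, 4000, seed=0)
        fit = um.fit_binding_isotherm(ds)
        assert fit.kd_nM == pytest.approx(3.4, rel=0.1)
        assert fit.stderr_nM > 0
        assert len(fit.fractions) == 8

    def test_agrees_with_lmfit_cross_check(self):
        import lmfit

        ds = um.simulate_binding_titration(self.CONCS, 3.4, 500, seed=1)

        def resid(params, c, f):
            return f - c / (c + params["kd"])

        params = lmfit.Parameters()
        params.add("kd", value=5.0, min=0.0)
        out = lmfit.minimize(resid, params,
                             args=(ds.concentrations_nM, ds.fractions))
        fit = um.fit_binding_isotherm(ds)
        assert fit.kd_nM == pytest.approx(out.params["kd"].value, rel=1e-4)


class TestOccupancyTrend:
    def test_constant_occupancy_is_stable(self):
        trend = um.fit_occupancy_vs_time([0, 1200, 2400, 3600],
                                         [0.95, 0.95, 0.95, 0.95])
        assert trend.slope_per_s == pytest.approx(0.0, abs=1e-12)
        assert trend.stable

    def test_decay_detected(self):
        t = np.linspace(0, 3600, 20)
        trend = um.fit_occupancy_vs_time(t, 0.95 - 1e-4 * t)
        assert trend.slope_per_s < 0
        assert not trend.stable

    def test_stable_verdict_rate_under_noise(self):
        t = np.linspace(0, 3600, 20)
        stable = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            f = 0.95 + rng.normal(0, 0.01, t.size)
            stable += um.fit_occupancy_vs_time(t, f).stable
        assert stable >= 45  # >= 90% of seeds

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            um.fit_occupancy_vs_time([0.0], [0.5])


class TestPrecisionAccuracy:
    def test_exact_calls(self):
        assert um.precision_accuracy([10.0, 10.0], 10.0) == {"bias": 0.0,
                                                             "sd": 0.0}

    def test_closed_form(self):
        pa = um.precision_accuracy([9.0, 11.0], 10.0)
        assert pa["bias"] == 0.0
        assert pa["sd"] == pytest.approx(np.sqrt(2.0))

    def test_needs_two_calls(self):
        with pytest.raises(ValueError):
            um.precision_accuracy([10.0], 10.0)


class TestCenteringAndDirectionality:
    def test_dyad_at_midpoint_has_zero_deviation(self):
        summary = um.centering_statistic([150.0], tf_edge=100.0,
                                         template_end=200.0)
        assert summary.mean_deviation == 0.0

    def test_outliers_flagged_not_dropped_by_default(self):
        dyads = [150.0, 152.0, 148.0, 90.0]  # last one passed the TF
        keep = um.centering_statistic(dyads, 100.0, 200.0)
        assert keep.outlier_mask.tolist() == [False, False, False, True]
        drop = um.centering_statistic(dyads, 100.0, 200.0,
                                      exclude_outliers=True)
        assert abs(drop.mean_deviation) < abs(keep.mean_deviation)

    def test_tf_free_molecules_are_outliers(self):
        summary = um.centering_statistic([150.0, 150.0], 100.0, 200.0,
                                         tf_bound=[True, False])
        assert summary.outlier_mask.tolist() == [False, True]

    def test_unremodeled_ensemble_is_vacuous(self):
        table = pd.DataFrame({"initial_dyad": [400.0] * 5,
                              "final_dyad": [400.0] * 5,
                              "tf_final": [True] * 5})
        summary = um.directionality_and_eviction_summary(table, 307.0)
        assert summary["n_remodeled"] == 0
        assert np.isnan(summary["frac_toward_tf"])

    def test_displacement_classification(self):
        table = pd.DataFrame({
            "initial_dyad": [400.0, 400.0, 400.0],
            "final_dyad": [350.0, 470.0, 250.0],   # toward, away, passed
            "tf_final": [False, True, False]})
        s = um.directionality_and_eviction_summary(table, 307.0)
        assert s["n_remodeled"] == 3
        # the molecule that passed the TF also ends up closer to it
        assert s["frac_toward_tf"] == pytest.approx(2 / 3)
        assert s["frac_passed_tf"] == pytest.approx(1 / 3)
        assert s["frac_tf_retained"] == pytest.approx(1 / 3)
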