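"""Aggregation and effect-estimation stage."""

import warnings

import numpy as np
import pandas as pd
import pytest

from presspulse.trends import (
    ChlBiovolumeModel, MetricTrendModel, cycle_average_biovolume,
    estimate_displacement_ratio, fit_chl_biovolume, fit_metric_trends,
    null_metrics_table, permutation_pvalue, total_biovolume,
)

warnings.filterwarnings("ignore", module="statsmodels")


class TestCycleAverageBiovolume:
    def test_ref_design_yields_72_records(self, sim_timeseries, ref_design):
        out = cycle_average_biovolume(sim_timeseries, ref_design.pulse_days)
        assert len(out) == 72  # 3 treatments x 6 replicates x 4 periods
        assert set(out["period"]) == {"Baseline", "P1", "P2", "P3"}

    def test_constant_biovolume_gives_that_constant(self, sim_timeseries):
        ts = sim_timeseries.copy()
        ts["biovolume"] = 7.5
        out = cycle_average_biovolume(ts, (4, 40, 68))
        assert np.allclose(out["biovolume_mean"], 7.5)

    def test_matches_hand_means_on_known_fixture(self):
        ts = pd.DataFrame({
            "treatment": "t", "replicate": "r",
            "day": [0, 2, 6, 8, 42, 70, 72],
            "biovolume": [1.0, 3.0, 10.0, 20.0, 5.0, 8.0, 4.0],
        })
        out = cycle_average_biovolume(ts, (4, 40, 68)).set_index("period")
        assert out.loc["Baseline", "biovolume_mean"] == pytest.approx(2.0)
        assert out.loc["P1", "biovolume_mean"] == pytest.approx(15.0)
        assert out.loc["P2", "biovolume_mean"] == pytest.approx(5.0)
        assert out.loc["P3", "biovolume_mean"] == pytest.approx(6.0)

    def test_empty_period_raises(self):
        ts = pd.DataFrame({"treatment": "t", "replicate": "r",
                           "day": [50, 52], "biovolume": [1.0, 2.0]})
        with pytest.raises(ValueError, match="empty period"):
            cycle_average_biovolume(ts, (4, 40, 68))


class TestTotalBiovolume:
    def test_zero_and_single_bin(self):
        assert total_biovolume([0.0, 0.0, 0.0]) == 0.0
        assert total_biovolume([0.0, 42.0, 0.0]) == 42.0

    def test_technical_counts_averaged_then_binned_sum(self):
        counts = np.array([[1.0, 2.0, 3.0],
                           [3.0, 2.0, 1.0],
                           [2.0, 2.0, 2.0]])
        assert total_biovolume(counts) == pytest.approx(6.0)

    def test_equals_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(0)
        counts = rng.gamma(2.0, 5.0, size=(3, 40))
        brute = sum(counts.mean(axis=0)[b] for b in range(40))
        assert total_biovolume(counts) == pytest.approx(brute)

    def test_negative_bins_rejected(self):
        with pytest.raises(ValueError):
            total_biovolume([1.0, -0.1])


def _chl_bv_data(slopes, intercepts, n=40, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for trt, (s, b) in zip(slopes.keys(), zip(slopes.values(), intercepts.values())):
        bv = rng.uniform(1.0, 20.0, size=n)
        chl = b + s * bv + rng.normal(0.0, noise, size=n)
        rows.append(pd.DataFrame({"treatment": trt, "biovolume": bv,
                                  "chl_total": chl}))
    return pd.concat(rows, ignore_index=True)


class TestChlBiovolumeRegression:
    def test_noiseless_coefficients_recovered_exactly(self):
        slopes = {"control": 0.8, "mid": 1.2, "strong": 1.5}
        intercepts = {"control": 2.0, "mid": 3.0, "strong": 1.0}
        fit = fit_chl_biovolume(_chl_bv_data(slopes, intercepts), log10=False)
        assert fit.r_squared == pytest.approx(1.0)
        for trt in slopes:
            assert fit.slopes[trt] == pytest.approx(slopes[trt], abs=1e-9)
            assert fit.intercepts[trt] == pytest.approx(intercepts[trt], abs=1e-8)

    def test_interaction_contrast_recovers_slope_difference(self):
        delta = 0.6
        df = _chl_bv_data({"control": 1.0, "enr": 1.0 + delta},
                          {"control": 2.0, "enr": 2.0}, n=150, noise=0.5, seed=3)
        fit = fit_chl_biovolume(df, log10=False)
        est, p = fit.interaction["enr"]
        se = 0.5 / np.sqrt(150)  # rough scale for the CI sanity band
        assert abs(est - delta) < 6 * se
        assert p < 0.01

    def test_null_interaction_rarely_significant(self):
        hits = 0
        for seed in range(40):
            df = _chl_bv_data({"control": 1.0, "enr": 1.0},
                              {"control": 2.0, "enr": 2.0},
                              n=30, noise=1.0, seed=seed)
            fit = fit_chl_biovolume(df, log10=False)
            hits += fit.interaction["enr"][1] < 0.05
        assert hits <= 8  # ~5% expected over 40 null fits

    def test_needs_three_points_per_treatment(self):
        df = _chl_bv_data({"control": 1.0, "enr": 1.0},
                          {"control": 0.0, "enr": 0.0}, n=2)
        with pytest.raises(ValueError, match="3 points"):
            fit_chl_biovolume(df)

    def test_estimator_facade_predicts(self):
        df = _chl_bv_data({"control": 0.5, "enr": 1.5},
                          {"control": 1.0, "enr": 2.0})
        model = ChlBiovolumeModel(log10=False).fit(df)
        pred = model.predict(df)
        np.testing.assert_allclose(pred, df["chl_total"], rtol=1e-8)


class TestMetricTrends:
    def test_single_cycle_raises(self):
        df = null_metrics_table(n_cycles=1)
        with pytest.raises(ValueError, match="at least 2"):
            fit_metric_trends(df)

    def test_marginal_never_exceeds_conditional(self, sim_metrics):
        fits = fit_metric_trends(sim_metrics)
        for fit in fits.values():
            assert 0.0 <= fit.var_marginal <= fit.var_conditional <= 1.0

    def test_control_is_reference_level(self, sim_metrics):
        fit = fit_metric_trends(sim_metrics, responses=("d0",))["d0"]
        names = list(fit.coefficients)
        assert not any("[T.control]" in n for n in names)
        assert any("[T.mid]" in n for n in names)

    def test_trend_power_on_declining_recovery(self):
        """Metrics generated with rc_scaled declining by one unit per cycle:
        the negative pulse-count effect is detected in >90% of runs."""
        detected = 0
        n_runs = 40
        for seed in range(n_runs):
            df = null_metrics_table(seed=seed, baseline=6.0)
            df["rc_scaled"] = df["rc_scaled"] - 1.0 * (df["cycle_id"] - 1)
            e = fit_metric_trends(df, responses=("rc_scaled",))[
                "rc_scaled"].effect("n_perturbations")
            detected += (e.estimate < 0) and (e.p_value < 0.05)
        assert detected > 0.9 * n_runs

    def test_type_one_error_rate_near_alpha(self):
        hits = 0
        n_runs = 60
        for seed in range(n_runs):
            df = null_metrics_table(seed=10_000 + seed)
            e = fit_metric_trends(df, responses=("rs_scaled",))[
                "rs_scaled"].effect("n_perturbations")
            hits += e.p_value < 0.05
        assert hits <= 0.15 * n_runs  # loose guard; exact band in acceptance

    def test_parameter_recovery_headline_contrast(self, sim_metrics):
        """On simulator output the enriched:control displacement ratio is
        about the built-in capacity doubling while rescaled resistance shows
        no treatment effect."""
        ratio = estimate_displacement_ratio(sim_metrics)
        assert 1.4 < ratio < 2.6
        e = fit_metric_trends(sim_metrics, responses=("rs_scaled",))[
            "rs_scaled"].effect("eutrophication")
        assert e.p_value > 0.05

    def test_estimator_facade(self, sim_metrics):
        model = MetricTrendModel(response="rc_scaled").fit(sim_metrics)
        assert model.model_kind_ in {"mixed", "mixed-intercept", "ols"}
        assert model.effect("n_perturbations").metric_name == "rc_scaled"
        assert model.var_marginal_ <= model.var_conditional_

    def test_permutation_pvalue_matches_null(self):
        df = null_metrics_table(seed=5)
        p = permutation_pvalue(df, "rs_scaled", term="eutrophication",
                               n_permutations=200, seed=0)
        assert p > 0.05

    def test_log10_requires_positive_response(self, sim_metrics):
        bad = sim_metrics.copy()
        bad.loc[bad.index[0], "d0"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_metric_trends(bad, responses=("d0",), log10=True)
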