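import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import stcr
from conftest import make_plots

TRUTH_FIELDS = ("nr_alone", "nr_integrated", "cs_pct", "cf_alone_pct",
                "cf_integrated_pct", "com_pct")


class TestEstimators:
    def test_nutrient_requirement_is_mean_uptake_per_yield(self):
        plots = make_plots([
            {"fert_n": 35, "yield_t": 10.0, "uptake_n": 61.0},
            {"fert_n": 35, "yield_t": 5.0, "uptake_n": 30.5},
        ])
        assert stcr.estimate_nutrient_requirement(plots, "n") == pytest.approx(6.10)

    def test_nutrient_requirement_needs_eligible_plots(self):
        plots = make_plots([{"fert_n": 0.0}])  # control only
        with pytest.raises(stcr.EstimationError, match="alone"):
            stcr.estimate_nutrient_requirement(plots, "n", "alone")

    def test_soil_contribution_from_controls(self):
        plots = make_plots([{"stv_n": 280.0, "uptake_n": 29.876}])
        assert stcr.estimate_soil_contribution(plots, "n") == pytest.approx(10.67)

    def test_soil_contribution_zero_uptake(self):
        plots = make_plots([{"uptake_n": 0.0}])
        assert stcr.estimate_soil_contribution(plots, "n") == 0.0

    def test_fertilizer_contribution_hand_value(self):
        plots = make_plots([{"fert_n": 52.5, "stv_n": 280.0, "uptake_n": 47.369}])
        cf = stcr.estimate_fertilizer_contribution(plots, 10.67, "n", "alone")
        assert cf == pytest.approx(33.32, abs=1e-3)

    def test_fertilizer_contribution_zero_when_soil_explains_uptake(self):
        plots = make_plots([{"fert_n": 35.0, "stv_n": 280.0, "uptake_n": 29.876}])
        assert stcr.estimate_fertilizer_contribution(plots, 10.67, "n") == \
            pytest.approx(0.0, abs=1e-12)

    def test_fym_contribution_hand_value(self):
        plots = make_plots([{"fym": 7.5, "fert_p": 35.0, "stv_n": 280.0,
                             "uptake_n": 35.5}])
        com = stcr.estimate_fym_contribution(plots, 10.67, 33.32, "n")
        assert com == pytest.approx(100 * 5.624 / 7500, abs=1e-6)
        assert com == pytest.approx(0.075, abs=1e-3)

    def test_fym_contribution_can_be_negative(self):
        plots = make_plots([{"fym": 7.5, "fert_p": 35.0, "stv_n": 280.0,
                             "uptake_n": 25.0}])
        assert stcr.estimate_fym_contribution(plots, 10.67, 33.32, "n") < 0

    def test_negative_per_plot_terms_not_clipped(self):
        """Averaging keeps negative per-plot contributions (unbiasedness)."""
        plots = make_plots([
            {"fert_n": 35.0, "stv_n": 280.0, "uptake_n": 29.876 + 7.0},
            {"fert_n": 35.0, "stv_n": 280.0, "uptake_n": 29.876 - 7.0},
        ])
        assert stcr.estimate_fertilizer_contribution(plots, 10.67, "n") == \
            pytest.approx(0.0, abs=1e-12)


class TestClosure:
    def test_zero_noise_calibration_recovers_truth_exactly(
            self, calibrated, zero_noise_truth):
        """The full estimator chain inverts the generative model."""
        for x in "npk":
            truth = zero_noise_truth.nutrient(x)
            for name in TRUTH_FIELDS:
                want = getattr(truth, name)
                assert calibrated.get(x, name) == pytest.approx(want, rel=1e-9), \
                    (x, name)

    def test_plot_counts_recorded(self, calibrated):
        assert calibrated.n_plots["n"]["nr_alone"] == 21
        assert calibrated.n_plots["n"]["nr_integrated"] == 42
        assert calibrated.n_plots["n"]["cs_pct"] == 4

    def test_strict_ledger_convention_lowers_integrated_cf(self, main_frame):
        lumped = stcr.calibrate_basic_parameters(main_frame)
        strict = stcr.calibrate_basic_parameters(
            main_frame, cf_integrated_convention="strict_ledger")
        for x in "npk":
            assert strict.cf_pct(x, "integrated") < lumped.cf_pct(x, "integrated")

    def test_parameters_round_trip_via_file(self, calibrated, tmp_path):
        path = tmp_path / "params.csv"
        stcr.write_table(calibrated, path)
        back = stcr.BasicParameters.from_file(path)
        for x in "npk":
            for name in TRUTH_FIELDS:
                assert back.get(x, name) == pytest.approx(
                    calibrated.get(x, name), rel=1e-9)

    def test_missing_uptake_on_yielding_plot_rejected(self, main_frame):
        frame = main_frame.copy()
        frame.loc[frame.index[0], "uptake_n"] = np.nan
        with pytest.raises(stcr.ValidationError, match="uptake"):
            stcr.calibrate_basic_parameters(frame)


class TestDescriptives:
    def test_hand_computed_summary(self):
        plots = make_plots([{"yield_t": v} for v in (2.0, 4.0, 6.0)])
        row = stcr.summarize_by_strip(plots, ["yield_t"]).iloc[0]
        assert (row["min"], row["max"], row["mean"]) == (2.0, 6.0, 4.0)
        assert row["sd"] == pytest.approx(2.0)
        assert row["cv_pct"] == pytest.approx(50.0)

    def test_constant_series(self):
        plots = make_plots([{"yield_t": 3.0}] * 3)
        row = stcr.summarize_by_strip(plots, ["yield_t"]).iloc[0]
        assert row["sd"] == 0.0 and row["cv_pct"] == 0.0

    def test_single_plot_gives_undefined_markers(self):
        row = stcr.summarize_by_strip(make_plots([{}]), ["yield_t"]).iloc[0]
        assert math.isnan(row["sd"]) and math.isnan(row["cv_pct"])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.1, 50.0), min_size=2, max_size=10))
    def test_matches_brute_force_formulas(self, values):
        plots = make_plots([{"yield_t": v} for v in values])
        row = stcr.summarize_by_strip(plots, ["yield_t"]).iloc[0]
        n, mean = len(values), sum(values) / len(values)
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
        assert row["mean"] == pytest.approx(mean, rel=1e-12)
        assert row["sd"] == pytest.approx(sd, rel=1e-9, abs=1e-12)
        if mean != 0:
            assert row["cv_pct"] == pytest.approx(100 * sd / mean, rel=1e-9,
                                                  abs=1e-9)


class TestCorrelation:
    def test_perfect_lines(self):
        up = make_plots([{"yield_t": v, "uptake_n": 2 * v + 1} for v in (1, 2, 3)])
        down = make_plots([{"yield_t": v, "uptake_n": 9 - v} for v in (1, 2, 3)])
        assert stcr.correlate_yield_uptake(up, "n")[0] == pytest.approx(1.0)
        assert stcr.correlate_yield_uptake(down, "n")[0] == pytest.approx(-1.0)

    def test_three_point_oracle(self):
        xs, ys = [1.0, 2.0, 3.0], [2.0, 3.0, 5.0]
        plots = make_plots([{"yield_t": x, "uptake_n": y} for x, y in zip(xs, ys)])
        mx, my = np.mean(xs), np.mean(ys)
        cov = np.mean([(x - mx) * (y - my) for x, y in zip(xs, ys)])
        want = cov / math.sqrt(np.var(xs) * np.var(ys))
        assert stcr.correlate_yield_uptake(plots, "n")[0] == pytest.approx(want)

    def test_zero_variance_undefined(self):
        plots = make_plots([{"yield_t": 2.0, "uptake_n": v} for v in (1, 2, 3)])
        r, r2 = stcr.correlate_yield_uptake(plots, "n")
        assert math.isnan(r) and math.isnan(r2)


class TestYieldRegression:
    def _linear_frame(self, rng, n, coef=(1.2, 3.4, -0.5), intercept=2.0,
                      noise=0.0):
        stv = rng.uniform(50, 400, size=(n, 3))
        y_kg = (intercept + stv @ np.array(coef)
                + noise * rng.standard_normal(n))
        return make_plots([
            {"stv_n": s[0], "stv_p": s[1], "stv_k": s[2], "yield_t": y / 1000.0}
            for s, y in zip(stv, y_kg)])

    def test_exact_linear_data_recovered(self):
        frame = self._linear_frame(np.random.default_rng(0), n=12)
        fit = stcr.fit_yield_regression(frame)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coefficients["stv_n"] == pytest.approx(1.2, rel=1e-9)
        assert fit.intercept == pytest.approx(2.0, abs=1e-6)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        frame = self._linear_frame(rng, n=5, noise=300.0)
        fit = stcr.fit_yield_regression(frame)
        X = np.column_stack([np.ones(5),
                             frame[["stv_n", "stv_p", "stv_k"]].to_numpy()])
        y = frame["yield_t"].to_numpy() * 1000.0
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        for b, name in zip(beta[1:], ("stv_n", "stv_p", "stv_k")):
            assert fit.coefficients[name] == pytest.approx(b, abs=1e-8)

    def test_singular_design_rejected(self):
        frame = make_plots([{"stv_n": 100.0, "stv_p": 50.0, "stv_k": 200.0,
                             "yield_t": v} for v in (1, 2, 3, 4, 5, 6)])
        with pytest.raises(stcr.EstimationError, match="[Ss]ingular"):
            stcr.fit_yield_regression(frame)

    def test_adjusted_r2_bounded_and_r2_affine_invariant(self):
        rng = np.random.default_rng(2)
        frame = self._linear_frame(rng, n=30, noise=500.0)
        fit = stcr.fit_yield_regression(frame)
        assert 0.0 <= fit.r2 <= 1.0
        assert fit.adj_r2 <= fit.r2
        rescaled = frame.copy()
        for col, (a, b) in {"stv_n": (2.0, 10.0), "stv_p": (0.5, -3.0),
                            "stv_k": (1.7, 100.0)}.items():
            rescaled[col] = a * rescaled[col] + b
        assert stcr.fit_yield_regression(rescaled).r2 == pytest.approx(
            fit.r2, rel=1e-9)

    def test_too_few_plots_rejected(self):
        with pytest.raises(stcr.EstimationError):
            stcr.fit_yield_regression(make_plots([{}] * 4))
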