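"""Calibration, recovery, repeatability, detection and summary statistics."""

import numpy as np
import pandas as pd
import pytest
from matplotlib import cbook

from mrmkit import quant
from mrmkit.quant import (
    boxplot_stats,
    column_summary,
    cv,
    detect,
    fit_calibration,
    lod_ladder,
    normalize_to_max,
    quantify,
    recovery,
    snr,
    species_call,
    transition_ratio,
)
from mrmkit.simulate import SimulationDesign, simulate_area_table, simulate_chromatogram


class TestNormalizeToMax:
    def test_row_scaling(self):
        df = pd.DataFrame([[49.0, 98.0]], columns=["a", "b"])
        out = normalize_to_max(df)
        assert out.values.tolist() == [[50.0, 100.0]]

    def test_idempotent_and_scale_invariant(self, rng):
        df = pd.DataFrame(rng.uniform(1, 100, size=(8, 5)))
        once = normalize_to_max(df)
        assert np.allclose(normalize_to_max(once), once)
        assert np.allclose(normalize_to_max(df * 7.3), once)

    def test_published_rows_already_normalized(self, extraction_screens):
        buffer_screen, time_screen = extraction_screens
        for screen in extraction_screens:
            assert np.allclose(normalize_to_max(screen), screen)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_max(pd.DataFrame([[0.0, 0.0]]))


class TestColumnSummary:
    def test_constant_matrix_ties_count_every_column(self):
        df = pd.DataFrame(np.full((4, 3), 100.0))
        out = column_summary(df)
        assert (out["maxima"] == 4).all()

    def test_matches_bruteforce_oracle(self, rng):
        mat = rng.uniform(1, 100, size=(10, 6))
        mat[0, :3] = 100.0  # force a tie
        df = pd.DataFrame(mat)
        out = column_summary(df)
        for j in df.columns:
            assert out.loc[j, "mean"] == round(float(np.mean(mat[:, j])))
            oracle = sum(1 for i in range(10) if mat[i, j] == mat[i].max())
            assert out.loc[j, "maxima"] == oracle


class TestCalibration:
    def test_noiseless_line_recovered(self):
        pts = [(l, 2.0 * l) for l in (0.1, 0.4, 0.7, 1.0)]
        c = fit_calibration(pts)
        assert (c.slope, c.intercept) == (pytest.approx(2.0), pytest.approx(0.0))
        assert c.r_squared == pytest.approx(1.0)
        # fit -> quantify is the identity on the training points
        for l, a in pts:
            assert quantify(c, a) == pytest.approx(l, abs=1e-12)

    def test_two_points_flagged_low_n(self):
        c = fit_calibration([(0.1, 1.0), (2.5, 30.0)])
        assert c.low_n and c.r_squared == pytest.approx(1.0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 5.0), (1.0, 6.0)])

    def test_slope_recovered_under_noise(self, rng):
        levels = np.tile([0.1, 0.4, 0.7, 1.0, 1.3, 1.6, 1.9, 2.2, 2.5], 3)
        sigma = np.sqrt(np.log(1 + 0.05**2))
        areas = 1000.0 * levels * rng.lognormal(-0.5 * sigma**2, sigma, len(levels))
        c = fit_calibration(zip(levels, areas))
        assert c.slope == pytest.approx(1000.0, rel=0.10)

    def test_through_origin_option(self):
        c = fit_calibration([(1.0, 2.1), (2.0, 3.9)], through_origin=True)
        assert c.intercept == 0.0

    def test_zero_slope_not_invertible(self):
        c = quant.CalibrationResult(slope=0.0, intercept=1.0, r_squared=0.0, n_points=3)
        with pytest.raises(ValueError):
            quantify(c, 5.0)


class TestRecovery:
    @pytest.mark.parametrize(
        "est,true,pct,in_band",
        [
            (0.85, 0.85, 100.0, True),
            (1.02, 0.85, 120.0, True),  # boundary inclusive
            (0.68, 0.85, 80.0, True),
            (0.6, 0.85, 70.588, False),
        ],
    )
    def test_band(self, est, true, pct, in_band):
        got_pct, got_band = recovery(est, true)
        assert got_pct == pytest.approx(pct, abs=0.01)
        assert got_band is in_band

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            recovery(1.0, 0.0)


class TestRepeatability:
    def test_cv_basics(self):
        assert cv([10, 10, 10]) == 0.0
        with pytest.raises(ValueError):
            cv([5.0])
        with pytest.raises(ValueError):
            cv([-1.0, 1.0])

    def test_transition_ratio_uses_rank_order(self):
        assert transition_ratio([100.0, 50.0, 20.0]) == pytest.approx(0.2)

    def test_cv_estimate_matches_simulation_truth(self, rng):
        sigma = np.sqrt(np.log(1 + 0.15**2))
        vals = rng.lognormal(mean=5.0, sigma=sigma, size=70)
        assert cv(vals) == pytest.approx(15.0, abs=5.0)


class TestDetection:
    def test_threshold_inclusive(self):
        assert detect([3.0, 3.0, 3.0]) is True
        assert detect([10.0, 10.0, 2.9]) is False
        with pytest.raises(ValueError):
            detect([3.0, 3.0])

    def test_species_rules(self):
        flags = {"m1": True, "m2": True, "m3": False}
        assert species_call("soy", flags, rule="all3").species_confirmed is False
        assert species_call("soy", flags, rule="any1").species_confirmed is True
        with pytest.raises(ValueError):
            species_call("soy", flags, rule="mostly")

    def test_lod_ladder_matches_closed_form(self):
        # signal = k * level over fixed noise: detected iff k*level/noise >= 3
        k, noise = 9000.0, 10.0
        levels = [0.001, 0.004, 0.01, 0.1]
        calls = {lvl: detect([k * lvl / noise] * 3) for lvl in levels}
        predicted = min(lvl for lvl in levels if k * lvl / noise >= 3.0)
        assert lod_ladder(calls) == predicted

    def test_nonmonotone_ladder_warns(self):
        with pytest.warns(UserWarning, match="non-monotone"):
            assert lod_ladder({0.1: True, 0.4: False, 0.7: True}) == 0.1

    def test_nothing_detected_returns_none(self):
        assert lod_ladder({0.1: False}) is None


class TestSnr:
    def trace(self, height, seed=0, noise_sd=10.0):
        return simulate_chromatogram(
            t_r_s=60.0, height=height, width_s=5.0, noise_sd=noise_sd,
            baseline=50.0, n_points=1200, duration_s=120.0, seed=seed,
        )

    def windows(self):
        dt = 120.0 / 1199
        return (int(45 / dt), int(75 / dt)), (0, int(30 / dt))

    def test_boundary_peak(self):
        _, y = self.trace(30.0, seed=3)
        pw, nw = self.windows()
        assert snr(y, pw, nw) == pytest.approx(3.0, rel=0.10)

    def test_blank_below_threshold(self):
        _, y = self.trace(0.0, seed=4)
        pw, nw = self.windows()
        assert snr(y, pw, nw) < 3.0

    def test_linear_in_height(self):
        pw, nw = self.windows()
        heights = np.array([10.0, 30.0, 60.0, 120.0])
        est = np.array(
            [np.mean([snr(self.trace(h, seed=s)[1], pw, nw) for s in range(10)])
             for h in heights]
        )
        slope = np.polyfit(heights / 10.0, est, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.10)

    def test_window_validation(self):
        _, y = self.trace(30.0)
        with pytest.raises(ValueError):
            snr(y, (100, 400), (300, 500))  # overlapping
        with pytest.raises(ValueError):
            snr(y, (100, 400), (500, 505))  # noise window too short


class TestBoxplotStats:
    def test_small_example(self):
        assert boxplot_stats([1, 2, 3])["median"] == 2.0

    def test_constant_vector(self):
        s = boxplot_stats([5.0] * 10)
        assert s["q1"] == s["q3"] == s["median"] == 5.0
        assert s["outliers"] == []

    def test_matches_matplotlib_oracle(self, rng):
        for _ in range(10):
            vals = rng.normal(0, 1, size=int(rng.integers(5, 200)))
            mine = boxplot_stats(vals)
            ref = cbook.boxplot_stats(vals, whis=1.5)[0]
            assert mine["median"] == pytest.approx(ref["med"])
            assert mine["q1"] == pytest.approx(ref["q1"])
            assert mine["q3"] == pytest.approx(ref["q3"])
            assert mine["whislo"] == pytest.approx(ref["whislo"])
            assert mine["whishi"] == pytest.approx(ref["whishi"])
            assert sorted(mine["outliers"]) == pytest.approx(sorted(ref["fliers"]))


class TestQuantifyTable:
    def test_noiseless_table_quantifies_exactly(self):
        design = SimulationDesign(noise_cv=0.0, seed=5)
        table, truth = simulate_area_table(design)
        curves, results = quant.quantify_table(table)
        for marker, curve in curves.items():
            assert curve.slope == pytest.approx(truth["slopes"][marker], rel=1e-9)
            assert curve.r_squared == pytest.approx(1.0)
        known = results.dropna(subset=["recovery_pct"])
        assert np.allclose(known["recovery_pct"], 100.0)

    def test_median_recovery_in_band_at_ten_percent_cv(self):
        design = SimulationDesign(noise_cv=0.10, seed=6)
        table, _ = simulate_area_table(design)
        _, results = quant.quantify_table(table)
        rec = results.dropna(subset=["recovery_pct"])
        for level, group in rec.groupby("true_level"):
            assert 80.0 <= group["recovery_pct"].median() <= 120.0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            quant.quantify_table(pd.DataFrame({"sample_id": []}))

    def test_repeatability_report(self):
        design = SimulationDesign(noise_cv=0.10, seed=7)
        table, _ = simulate_area_table(design)
        one_level = table[(table["role"] == "unknown") & (table["level"] == 2.35)]
        reports = quant.repeatability_report(one_level)
        assert len(reports) == len(design.markers)
        for r in reports:
            assert r.n == 12
            assert 0 <= r.area_cv_pct < 50
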