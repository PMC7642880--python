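"""Inverse regression fitting and the seven fitting-subset strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from addhrv import (
    CalibrationSegment,
    MethodConfig,
    Scope,
    config_for,
    find_movement_bins,
    fit_method,
    fit_regression,
    select_fitting_subsets,
)
from addhrv.simulate import SimParams, simulate_cohort

from conftest import make_grid


def ols_oracle(x, y):
    """Closed-form two-parameter least squares, independent of the fit path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    b1 = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    return ym - b1 * xm, b1


SCOPE = Scope("session")


class TestFitRegression:
    def test_hand_worked_three_point_fit(self):
        # exact line rmssd = 50 - 20*acc; SD of (50,40,30) is 10, SEM 10/sqrt(3)
        fit = fit_regression([0.0, 0.5, 1.0], [50.0, 40.0, 30.0], SCOPE)
        assert fit.b0_ms == pytest.approx(50.0)
        assert fit.b1 == pytest.approx(-20.0)
        assert fit.sem_ms == pytest.approx(10.0 / np.sqrt(3), abs=1e-4)
        assert fit.valid and fit.n == 3

    def test_constant_rmssd_zero_slope_zero_sem(self):
        fit = fit_regression([0.1, 0.2, 0.3], [42.0, 42.0, 42.0], SCOPE)
        assert fit.b0_ms == pytest.approx(42.0)
        assert fit.b1 == pytest.approx(0.0)
        assert fit.sem_ms == pytest.approx(0.0)

    def test_constant_acceleration_is_degenerate_not_error(self):
        fit = fit_regression([0.2, 0.2, 0.2], [50.0, 40.0, 30.0], SCOPE)
        assert not fit.valid

    def test_single_sample_is_degenerate(self):
        assert not fit_regression([0.2], [50.0], SCOPE).valid

    def test_empty_subset_errors(self):
        with pytest.raises(ValueError, match="empty"):
            fit_regression([], [], SCOPE)

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 40))
    def test_matches_closed_form_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, n)
        if np.unique(x).size < 2:
            x[0] += 1.0
        y = rng.uniform(20, 90, n)
        fit = fit_regression(x, y, SCOPE)
        b0, b1 = ols_oracle(x, y)
        assert fit.b0_ms == pytest.approx(b0, rel=1e-9, abs=1e-9)
        assert fit.b1 == pytest.approx(b1, rel=1e-9, abs=1e-9)
        assert fit.sem_ms == pytest.approx(np.std(y, ddof=1) / np.sqrt(n), rel=1e-9)

    def test_sem_invariant_under_permutation(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(0, 1, 30), rng.uniform(20, 90, 30)
        perm = rng.permutation(30)
        assert fit_regression(x, y, SCOPE).sem_ms == pytest.approx(
            fit_regression(x[perm], y[perm], SCOPE).sem_ms, rel=1e-12
        )


def full_day_grid(hours=24, rng=None, days=1):
    rng = rng or np.random.default_rng(0)
    n = int(hours * 120) * days if days == 1 else days * 2880
    acc = rng.uniform(0, 0.8, n)
    return make_grid(55.0 - 25.0 * acc, acc)


class TestSelectSubsets:
    def test_hourly10_yields_one_model_per_hour(self):
        subsets = select_fitting_subsets(full_day_grid(), config_for("hourly10"))
        assert len(subsets) == 24
        assert all(len(sel) == 20 for _, sel in subsets)
        # first 10 min of each hour by wall clock
        scope, sel = subsets[3]
        assert (scope.day, scope.hour) == (1, 3)
        assert list(sel) == list(range(3 * 120, 3 * 120 + 20))

    def test_threehour10_interior_and_edge_sizes(self):
        subsets = dict(
            (s.hour, sel) for s, sel in select_fitting_subsets(full_day_grid(), config_for("threehour10"))
        )
        assert len(subsets) == 24
        assert len(subsets[12]) == 60  # 30 min worth of data
        assert len(subsets[0]) == 40  # first+second hour
        assert len(subsets[23]) == 40  # penultimate+final hour
        assert set(subsets[0]) == set(range(20)) | set(range(120, 140))
        assert set(subsets[23]) == set(range(22 * 120, 22 * 120 + 20)) | set(
            range(23 * 120, 23 * 120 + 20)
        )

    def test_full_per_day_and_per_session(self):
        grid = full_day_grid(days=3)
        per_day = select_fitting_subsets(grid, config_for("full"))
        assert [s.day for s, _ in per_day] == [1, 2, 3]
        assert all(len(sel) == 2880 for _, sel in per_day)
        whole = select_fitting_subsets(grid, config_for("full", full_scope="session"))
        assert len(whole) == 1 and len(whole[0][1]) == 3 * 2880

    def test_nextday_skips_first_day(self):
        subsets = select_fitting_subsets(full_day_grid(days=3), config_for("nextday"))
        assert [s.day for s, _ in subsets] == [2, 3]
        assert [s.kind for s, _ in subsets] == ["previous-day"] * 2
        # fit on the previous day's windows
        assert subsets[0][1].min() == 0 and subsets[0][1].max() == 2879
        assert len(subsets[0][1]) == 2880

    def test_nextday_single_day_has_no_subsets(self):
        assert select_fitting_subsets(full_day_grid(), config_for("nextday")) == []

    def test_calibration_requires_segments(self):
        with pytest.raises(ValueError, match="calibration"):
            select_fitting_subsets(full_day_grid(), config_for("calibration"))

    def test_calibration_excludes_stress_tasks_extended_includes(self):
        grid = full_day_grid()
        segs = [
            CalibrationSegment("P01", act, 180.0 * i, 180.0 * (i + 1))
            for i, act in enumerate(
                ["sit_video", "stand_count", "lie_count", "cycle", "clench_tense", "read_aloud", "stairs"]
            )
        ]
        (_, plain), = select_fitting_subsets(grid, config_for("calibration"), segs)
        (_, ext), = select_fitting_subsets(grid, config_for("calibration_extended"), segs)
        assert len(plain) == 5 * 6  # five activities x 6 windows of 30 s
        assert len(ext) == 7 * 6
        clench_read = set(range(4 * 6, 6 * 6))
        assert clench_read.isdisjoint(plain) and clench_read.issubset(ext)

    def test_subset_positions_independent_of_values(self):
        g1 = full_day_grid(rng=np.random.default_rng(1))
        g2 = full_day_grid(rng=np.random.default_rng(2))
        for method in ("hourly10", "threehour10", "full", "nextday"):
            s1 = select_fitting_subsets(g1, config_for(method))
            s2 = select_fitting_subsets(g2, config_for(method))
            assert [(s, list(sel)) for s, sel in s1] == [(s, list(sel)) for s, sel in s2]


class TestMovementBins:
    def brute_force_bins(self, grid, cfg):
        """Independent scan over every candidate run."""
        f = grid.frame
        acc = f["acc_g"].to_numpy()
        present = ~(f["rmssd_ms"].isna() | f["acc_g"].isna()).to_numpy()
        p25, p50, p75 = np.percentile(acc[present], [25, 50, 75])
        ranges = [(-np.inf, p25), (p25, p50), (p50, p75), (p75, np.inf)]
        L = cfg.bin_windows
        out = {}
        for q, (lo, hi) in enumerate(ranges, start=1):
            for start in range(len(acc) - L + 1):
                window = acc[start : start + L]
                ok = present[start : start + L].all() and (
                    (window >= lo) & (window < hi) if q < 4 else (window >= lo)
                ).all()
                if ok:
                    out[q] = (start, L)
                    break
        return out

    def _engineered_grid(self):
        rng = np.random.default_rng(3)
        acc = rng.uniform(0, 1, 480)
        # plant one clean 10-window run per quartile at known offsets
        p = np.percentile(acc, [25, 50, 75])
        levels = [p[0] / 2, (p[0] + p[1]) / 2, (p[1] + p[2]) / 2, (p[2] + 1.0) / 2]
        offsets = [40, 140, 240, 340]
        for lvl, off in zip(levels, offsets):
            acc[off : off + 10] = lvl
        return make_grid(np.full(480, 50.0), acc), offsets

    def test_engineered_runs_found_and_match_brute_force(self):
        grid, _ = self._engineered_grid()
        cfg = MethodConfig(method="bins")
        bins = find_movement_bins(grid, cfg)
        expected = self.brute_force_bins(grid, cfg)
        assert {b.quartile: (b.start_index, b.length) for b in bins} == expected
        assert len(bins) == 4
        assert sum(b.length for b in bins) == 40  # max 20 min worth of data

    def test_missing_quartile_absent(self):
        # alternate between two low values and two high values so the middle
        # quartiles never accumulate 5 consecutive minutes
        acc = np.tile(np.r_[np.full(10, 0.05), np.full(10, 0.9)], 24).astype(float)
        acc[::7] += 0.01  # enough distinct values for percentiles
        grid = make_grid(np.full(480, 50.0), acc)
        bins = find_movement_bins(grid, MethodConfig(method="bins"))
        quartiles = {b.quartile for b in bins}
        assert 4 in quartiles and len(quartiles) < 4
        assert sum(b.length for b in bins) == 10 * len(bins)

    def test_constant_acceleration_errors(self):
        grid = make_grid(np.full(100, 50.0), np.full(100, 0.2))
        with pytest.raises(ValueError, match="distinct"):
            find_movement_bins(grid, MethodConfig(method="bins"))


class TestFitMethod:
    def test_full_single_day_fits_all_windows(self):
        fits = fit_method(full_day_grid(), config_for("full"))
        assert len(fits) == 1 and fits[0].n == 2880

    def test_missing_hour_gives_invalid_fit(self):
        grid = full_day_grid()
        rows = grid.frame["hour"] == 5
        grid.frame.loc[rows, "rmssd_ms"] = np.nan
        fits = fit_method(grid, config_for("hourly10"))
        by_hour = {f.scope.hour: f for f in fits}
        assert not by_hour[5].valid
        assert by_hour[6].valid

    @pytest.mark.parametrize(
        "method", ["hourly10", "full", "threehour10", "bins", "calibration", "nextday"]
    )
    def test_noiseless_grid_recovers_generating_line(self, method):
        rng = np.random.default_rng(4)
        n = 2 * 2880
        acc = rng.uniform(0, 0.8, n)
        grid = make_grid(55.0 - 25.0 * acc, acc)
        calib = [
            CalibrationSegment("P01", act, 180.0 * i, 180.0 * (i + 1))
            for i, act in enumerate(
                ["sit_video", "stand_count", "lie_count", "cycle", "clench_tense", "read_aloud", "stairs"]
            )
        ]
        for fit in fit_method(grid, config_for(method), calib):
            if fit.valid:
                assert fit.b0_ms == pytest.approx(55.0, abs=1e-8)
                assert fit.b1 == pytest.approx(-25.0, abs=1e-8)

    def test_every_method_recovers_line_on_clean_simulation(self, clean_day):
        # generator's movement-only world: every strategy's valid fits agree
        # with the generating participant line
        truth = clean_day.truth
        for method in ("hourly10", "full", "threehour10", "bins", "calibration_extended", "calibration"):
            fits = fit_method(clean_day.grid, config_for(method), clean_day.calibration)
            valid = [f for f in fits if f.valid]
            assert valid, method
            for f in valid:
                assert f.b0_ms == pytest.approx(truth.b0_ms, abs=1e-6)
                assert f.b1 == pytest.approx(truth.b1, abs=1e-6)
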