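"""HRV index extraction: artifact gating, SDNN, Lorenz-plot CSI/CVI, windowing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadcrp.hrv import (
    LorenzAxes,
    RRSeries,
    clean_rr,
    csi_cvi,
    lorenz_axes,
    sdnn,
    sliding_indices,
)


def make_rr(intervals_ms, subject="s"):
    t = np.cumsum(np.asarray(intervals_ms, dtype=float)) / 1000.0
    return RRSeries(subject, t, intervals_ms)


class TestCleanRR:
    def test_out_of_range_interval_removed_and_flagged(self):
        nn = clean_rr(make_rr([800, 810, 50, 790]), 300, 2000, 0.3)
        assert nn.intervals.tolist() == [800, 810, 790]
        assert nn.artifact_fraction == pytest.approx(0.25)
        assert nn.flagged  # 25% > 5% gate

    def test_clean_series_untouched(self):
        nn = clean_rr(make_rr([800, 800, 800]))
        assert nn.intervals.tolist() == [800, 800, 800]
        assert nn.artifact_fraction == 0.0
        assert not nn.flagged

    def test_six_percent_artifacts_exceed_gate(self):
        ivs = [800.0] * 94 + [100.0] * 6  # 6/100 out of range
        nn = clean_rr(make_rr(ivs))
        assert nn.artifact_fraction == pytest.approx(0.06)
        assert nn.flagged

    def test_jump_versus_running_median(self):
        # 1200 ms differs from the median of previous kept (800) by 50% > 30%
        nn = clean_rr(make_rr([800, 810, 1200, 805]), 300, 2000, 0.3)
        assert 1200 not in nn.intervals

    def test_empty_and_bad_params_raise(self):
        with pytest.raises(ValueError, match="empty"):
            RRSeries("s", np.array([]), np.array([]))
        with pytest.raises(ValueError):
            clean_rr(make_rr([800, 800]), min_ms=0, max_ms=2000)
        with pytest.raises(ValueError):
            clean_rr(make_rr([800, 800]), jump_frac=1.5)

    @given(
        st.lists(st.floats(min_value=100, max_value=3000), min_size=1, max_size=60)
    )
    @settings(max_examples=50, deadline=None)
    def test_never_reorders_never_invents(self, intervals):
        intervals = [round(i, 1) for i in intervals]
        rr = make_rr(intervals)
        nn = clean_rr(rr)
        assert 0.0 <= nn.artifact_fraction <= 1.0
        # kept samples are a subsequence of the input (matched by time)
        pos = np.searchsorted(rr.times, nn.times)
        assert np.allclose(rr.times[pos], nn.times)
        assert np.allclose(rr.intervals[pos], nn.intervals)
        assert np.all(np.diff(pos) > 0) or len(nn) <= 1


class TestSdnn:
    @pytest.mark.parametrize(
        "window, expected",
        [
            ([800, 810, 790, 800], 8.164966),
            ([820] * 50, 0.0),
            ([750, 850], 70.710678),
        ],
    )
    def test_worked_examples(self, window, expected):
        assert sdnn(window) == pytest.approx(expected, abs=1e-5)

    def test_single_beat_is_missing(self):
        assert math.isnan(sdnn([800]))

    def test_matches_two_pass_oracle(self, rng):
        for _ in range(30):
            w = rng.normal(850, 60, size=rng.integers(2, 200))
            mean = sum(w) / len(w)
            oracle = math.sqrt(sum((x - mean) ** 2 for x in w) / (len(w) - 1))
            assert sdnn(w) == pytest.approx(oracle, abs=1e-9)


class TestLorenz:
    def test_symmetric_ramp(self):
        ax = lorenz_axes([800, 850, 900, 850, 800])
        assert ax.sd1 == pytest.approx(40.8248, abs=1e-3)
        assert ax.sd2 == pytest.approx(40.8248, abs=1e-3)
        assert ax.T == pytest.approx(163.299, abs=1e-2)
        assert ax.L == pytest.approx(163.299, abs=1e-2)
        assert ax.n_pairs == 4

    def test_constant_window_degenerate(self):
        ax = lorenz_axes([820] * 10)
        assert ax.T == 0 and ax.L == 0

    def test_perfect_alternation_collapses_longitudinal_axis(self):
        ax = lorenz_axes([700, 900, 700, 900, 700])  # sums constant
        assert ax.L == pytest.approx(0.0, abs=1e-9)
        assert ax.sd2 == pytest.approx(0.0, abs=1e-9)

    def test_too_few_pairs_missing(self):
        assert math.isnan(lorenz_axes([800, 810]).sd1)

    def test_csi_cvi_closed_form(self):
        csi, cvi = csi_cvi(LorenzAxes(T=100, L=400, sd1=25, sd2=100, n_pairs=10))
        assert csi == pytest.approx(4.0)
        assert cvi == pytest.approx(math.log10(100 * 400), abs=1e-9)

    def test_csi_one_under_symmetry_and_degenerate_missing(self):
        csi, _ = csi_cvi(LorenzAxes(T=55.5, L=55.5, sd1=1, sd2=1, n_pairs=5))
        assert csi == pytest.approx(1.0)
        csi, cvi = csi_cvi(LorenzAxes(T=0.0, L=10.0, sd1=0, sd2=2.5, n_pairs=5))
        assert math.isnan(csi) and math.isnan(cvi)

    def test_ar1_axis_ratio_tracks_autocorrelation(self, rng):
        # for AR(1) intervals: sd2^2/sd1^2 -> (1+phi)/(1-phi)
        phi, n = 0.6, 10_000
        z = np.empty(n)
        z[0] = rng.standard_normal()
        innov = rng.standard_normal(n - 1) * math.sqrt(1 - phi**2)
        for t in range(1, n):
            z[t] = phi * z[t - 1] + innov[t - 1]
        ax = lorenz_axes(900 + 40 * z)
        expected = (1 + phi) / (1 - phi)
        assert ax.sd2**2 / ax.sd1**2 == pytest.approx(expected, rel=0.10)


class TestSlidingIndices:
    def test_grid_layout_600s(self):
        ivs = [1000.0] * 600  # beats at 1 s .. 600 s exactly
        out = sliding_indices(clean_rr(make_rr(ivs)), width_s=300, step_s=60)
        assert out["SDNN"].grid.tolist() == [300, 360, 420, 480, 540, 600]
        assert set(out) == {"SDNN", "CSI", "CVI"}

    def test_sparse_window_missing(self):
        # beats only in the first 10 s of a 360 s span: the 360 s window
        # ending at 660 s has no beats at all
        t = np.array([1.0, 2.0, 3.0, 660.0])
        rr = RRSeries("s", t, np.array([1000.0] * 4))
        out = sliding_indices(clean_rr(rr), width_s=300, step_s=60)
        sd = out["SDNN"]
        assert bool(sd.missing[sd.grid == 360.0][0])

    def test_short_series_all_missing(self):
        out = sliding_indices(clean_rr(make_rr([800.0] * 10)))
        assert out["CSI"].missing.all()

    def test_width_not_multiple_of_step_raises(self):
        with pytest.raises(ValueError):
            sliding_indices(clean_rr(make_rr([800.0] * 10)), 250, 60)

    def test_stationary_beats_recover_process_std(self, rng):
        ivs = rng.normal(850, 25, size=1200).clip(400)
        out = sliding_indices(clean_rr(make_rr(ivs)))
        vals = out["SDNN"].values[~out["SDNN"].missing]
        assert np.median(vals) == pytest.approx(25, rel=0.15)
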