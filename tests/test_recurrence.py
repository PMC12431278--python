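"""Recurrence/cross-recurrence construction, quantification and imaging."""

import numpy as np
import pytest

from dyadcrp.recurrence import (
    RecurrenceConfig,
    build_crp,
    build_rp,
    cross_recurrence,
    diagonal_block_profile,
    dominant_period,
    recurrence_rate,
    tau_profile,
    to_image,
)

from conftest import make_discrete_segment


def brute_force_rp(levels, eps_levels=0):
    n = len(levels)
    out = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for j in range(n):
            if abs(levels[i] - levels[j]) <= eps_levels:
                out[i, j] = 1
    return out


class TestBuildRP:
    def test_three_point_example(self):
        rp = build_rp(make_discrete_segment([1, 2, 1]))
        expected = np.array([[1, 0, 1], [0, 1, 0], [1, 0, 1]], dtype=np.uint8)
        assert np.array_equal(rp.entries, expected)
        assert rp.entries.sum() == 5

    def test_main_diagonal_always_recurs(self, rng):
        rp = build_rp(make_discrete_segment(rng.integers(0, 11, 80)))
        assert np.all(np.diagonal(rp.entries) == 1)

    def test_symmetry(self, rng):
        rp = build_rp(make_discrete_segment(rng.integers(0, 11, 80)))
        assert np.array_equal(rp.entries, rp.entries.T)

    def test_requires_discrete_state(self):
        seg = make_discrete_segment([1, 2])
        seg.state = "normalized"
        with pytest.raises(ValueError, match="discrete"):
            build_rp(seg)

    def test_epsilon_widens_tolerance(self):
        seg = make_discrete_segment([0, 1, 5])
        strict = build_rp(seg, RecurrenceConfig(0.0))
        loose = build_rp(seg, RecurrenceConfig(0.1))  # |dlevel| <= 1
        assert strict.entries.sum() == 3
        assert loose.entries.sum() == 5
        assert np.all(loose.entries >= strict.entries)


class TestBuildCRP:
    def test_single_coincidence(self):
        m = make_discrete_segment([1, 2], subject="mom")
        c = make_discrete_segment([2, 3], subject="kid")
        crp = build_crp(m, c)
        # rows = child, cols = mother: child level 2 meets mother level 2
        assert crp.entries.tolist() == [[0, 1], [0, 0]]
        assert crp.is_cross

    def test_self_crp_equals_rp(self, rng):
        seg = make_discrete_segment(rng.integers(0, 11, 60))
        assert np.array_equal(build_crp(seg, seg).entries, build_rp(seg).entries)

    def test_swapping_members_transposes(self, rng):
        a = make_discrete_segment(rng.integers(0, 11, 40), subject="a")
        b = make_discrete_segment(rng.integers(0, 11, 40), subject="b")
        assert np.array_equal(build_crp(a, b).entries, build_crp(b, a).entries.T)

    def test_kind_and_length_mismatch_raise(self):
        a = make_discrete_segment([1, 2], kind="CVI")
        b = make_discrete_segment([1, 2], kind="CSI")
        with pytest.raises(ValueError, match="kind"):
            build_crp(a, b)
        c = make_discrete_segment([1, 2, 3], kind="CVI")
        with pytest.raises(ValueError, match="length"):
            build_crp(a, c)


class TestQuantification:
    def test_recurrence_rate_extremes_and_fraction(self):
        m = build_rp(make_discrete_segment([3, 3, 3]))
        assert recurrence_rate(m) == 1.0
        crp = build_crp(
            make_discrete_segment([0, 0], subject="a"),
            make_discrete_segment([10, 10], subject="b"),
        )
        assert recurrence_rate(crp) == 0.0
        assert recurrence_rate(build_rp(make_discrete_segment([1, 2, 1]))) == pytest.approx(5 / 9)

    def test_rate_monotone_in_epsilon(self, rng):
        seg = make_discrete_segment(rng.integers(0, 11, 100))
        rates = [
            recurrence_rate(build_rp(seg, RecurrenceConfig(e)))
            for e in (0.0, 0.1, 0.2, 0.5, 1.0)
        ]
        assert all(a <= b for a, b in zip(rates, rates[1:]))
        assert rates[-1] == 1.0

    def test_independent_sequences_rate_matches_level_frequencies(self, rng):
        n = 1440
        a = rng.integers(0, 4, n)
        b = rng.integers(0, 4, n)
        crp = build_crp(
            make_discrete_segment(a, subject="a"), make_discrete_segment(b, subject="b")
        )
        p = np.bincount(a, minlength=11) / n
        q = np.bincount(b, minlength=11) / n
        expected = float(p @ q)
        sigma = np.sqrt(expected * (1 - expected) / n**2)
        # n^2 cells are not independent; allow a generous multiple of the
        # binomial scale
        assert abs(recurrence_rate(crp) - expected) < 50 * sigma

    def test_tau_profile_parity_of_alternating_signal(self):
        rp = build_rp(make_discrete_segment([0, 1] * 30))
        prof = tau_profile(rp)
        assert np.allclose(prof[0::2], 1.0)
        assert np.allclose(prof[1::2], 0.0)

    def test_tau_profile_lag0_is_one(self, rng):
        rp = build_rp(make_discrete_segment(rng.integers(0, 11, 50)))
        assert tau_profile(rp)[0] == 1.0

    def test_tau_profile_requires_square(self):
        crp = build_crp(
            make_discrete_segment([1, 2], subject="a"),
            make_discrete_segment([1, 2], subject="b"),
        )
        prof = tau_profile(crp)  # square cross plot is fine
        assert prof.shape == (2,)
        with pytest.raises(ValueError, match="square"):
            tau_profile(np.zeros((3, 4), dtype=np.uint8))

    def test_sine_period_recovered_from_profile(self):
        # 0.4 Hz sine sampled at 100 Hz: first profile peak at 2.5 s
        fs = 100.0
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 0.4 * t)
        xn = (x - x.min()) / (x.max() - x.min())
        prof = tau_profile(cross_recurrence(xn, xn, 0.05))
        assert dominant_period(prof, dt=1 / fs) == pytest.approx(2.5, abs=0.05)

    def test_diagonal_block_profile_locates_synchrony(self):
        a = np.array([1, 1, 1, 1, 5, 5, 5, 5])
        b = np.array([1, 1, 1, 1, 9, 9, 9, 9])
        crp = build_crp(
            make_discrete_segment(a, subject="a"), make_discrete_segment(b, subject="b")
        )
        blocks = diagonal_block_profile(crp, block=4)
        assert blocks.tolist() == [1.0, 0.0]


class TestToImage:
    def test_block_means(self):
        m = build_rp(make_discrete_segment([1, 1, 2, 2]))
        img = to_image(m, 2)
        # blocks: [[1,1],[1,1]] -> 1; off-diagonal blocks of zeros -> 0
        assert img.pixels.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_factor_one_is_identity(self, rng):
        m = build_rp(make_discrete_segment(rng.integers(0, 11, 12)))
        assert np.array_equal(to_image(m, 1).pixels, m.entries.astype(float))

    def test_truncates_partial_blocks_and_validates_factor(self):
        m = build_rp(make_discrete_segment([1, 2, 3, 4, 5]))
        assert to_image(m, 2).pixels.shape == (2, 2)
        with pytest.raises(ValueError, match="factor"):
            to_image(m, 9)

    def test_pixels_in_unit_interval(self, rng):
        m = build_rp(make_discrete_segment(rng.integers(0, 11, 50)))
        px = to_image(m, 7).pixels
        assert px.min() >= 0.0 and px.max() <= 1.0


def test_builders_match_brute_force_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(5, 120))
        lv = rng.integers(0, 11, n)
        assert np.array_equal(
            build_rp(make_discrete_segment(lv)).entries, brute_force_rp(lv)
        )
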