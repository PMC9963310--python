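"""Recombination operator: alternation, interpolation weights, balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram

from pprdetect import (
    DAParams,
    augment_balanced,
    cut_points,
    recombine,
    smooth_cutpoint,
    spectral_similarity,
)
from pprdetect.windowing import CASES
from tests.conftest import make_ppr_window


def _rand_window(rng, case="whole", channels=3, wid="w"):
    return make_ppr_window(rng.standard_normal((channels, 500)), case=case, window_id=wid)


class TestGeometry:
    def test_default_cutpoints_on_500_samples(self):
        assert cut_points(500, 3) == [125, 250, 375]

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError, match="not divisible"):
            cut_points(500, 2)


class TestRecombine:
    def test_identical_parents_reproduce_themselves_exactly(self):
        rng = np.random.default_rng(0)
        a = _rand_window(rng, wid="a")
        b = make_ppr_window(a.data.copy(), window_id="a2")
        child = recombine(a, b)
        np.testing.assert_array_equal(child.data, a.data)

    def test_alternating_parent_of_origin(self):
        rng = np.random.default_rng(1)
        a, b = _rand_window(rng, wid="a"), _rand_window(rng, wid="b")
        c = recombine(a, b).data
        assert np.array_equal(c[:, 100], a.data[:, 100])  # segment 0 from A
        assert np.array_equal(c[:, 130], b.data[:, 130])  # segment 1 from B
        assert np.array_equal(c[:, 300], a.data[:, 300])  # segment 2 from A
        assert np.array_equal(c[:, 400], b.data[:, 400])  # segment 3 from B

    def test_exact_parent_match_outside_smoothing_neighbourhoods(self):
        rng = np.random.default_rng(2)
        a, b = _rand_window(rng, wid="a"), _rand_window(rng, wid="b")
        c = recombine(a, b).data
        seg_src = {0: a, 1: b, 2: a, 3: b}
        for k, parent in seg_src.items():
            for s in range(k * 125, (k + 1) * 125):
                near_cut = any(abs(s - x) <= 2 for x in (125, 250, 375))
                if not near_cut:
                    assert np.array_equal(c[:, s], parent.data[:, s]), s

    def test_constant_parent_interpolation_profile(self):
        """A=0, B=1: the child ramps (0, .25, .5, .75, 1) around each cut-point."""
        a = make_ppr_window(np.zeros((1, 500)), window_id="a")
        b = make_ppr_window(np.ones((1, 500)), window_id="b")
        c = recombine(a, b).data[0]
        np.testing.assert_allclose(c[123:128], [0.0, 0.25, 0.5, 0.75, 1.0])
        # cut 250 has B on the left and A on the right: mirrored ramp
        np.testing.assert_allclose(c[248:253], [1.0, 0.75, 0.5, 0.25, 0.0])
        np.testing.assert_allclose(c[373:378], [0.0, 0.25, 0.5, 0.75, 1.0])

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_convexity_child_bounded_by_parents(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _rand_window(rng, wid="a"), _rand_window(rng, wid="b")
        c = recombine(a, b).data
        lo = np.minimum(a.data, b.data)
        hi = np.maximum(a.data, b.data)
        assert np.all(c >= lo - 1e-12) and np.all(c <= hi + 1e-12)

    def test_channel_coherence_same_cut_pattern_on_all_channels(self):
        rng = np.random.default_rng(3)
        a, b = _rand_window(rng, channels=5, wid="a"), _rand_window(rng, channels=5, wid="b")
        c = recombine(a, b).data
        from_a = np.isclose(c, a.data)
        for ch in range(1, 5):
            np.testing.assert_array_equal(from_a[ch], from_a[0])

    def test_case_and_provenance_conserved(self):
        rng = np.random.default_rng(4)
        a, b = _rand_window(rng, case="onset", wid="a"), _rand_window(rng, case="onset", wid="b")
        child = recombine(a, b)
        assert child.ppr_case == "onset"
        assert child.provenance == "synthetic"
        assert child.parent_ids == ("a", "b")

    def test_mismatched_case_or_shape_rejected(self):
        rng = np.random.default_rng(5)
        a = _rand_window(rng, case="onset", wid="a")
        b = _rand_window(rng, case="whole", wid="b")
        with pytest.raises(ValueError, match="share a case"):
            recombine(a, b)
        c = make_ppr_window(np.zeros((2, 500)), case="onset", window_id="c")
        with pytest.raises(ValueError, match="identical shapes"):
            recombine(a, c)


class TestSmoothCutpoint:
    def test_interpolation_weights(self):
        A = np.full((1, 500), 4.0)
        B = np.zeros((1, 500))
        C = A.copy()
        smooth_cutpoint(C, A, B, 125)
        assert C[0, 124] == pytest.approx(3.0)  # 0.75*4 + 0.25*0
        assert C[0, 125] == pytest.approx(2.0)  # midpoint
        assert C[0, 127] == pytest.approx(0.0)  # B side

    def test_midpoint_of_two_and_six_is_four(self):
        A = np.full((1, 500), 2.0)
        B = np.full((1, 500), 6.0)
        C = np.empty_like(A)
        smooth_cutpoint(C, A, B, 250)
        assert C[0, 250] == pytest.approx(4.0)

    def test_equal_parents_unchanged_across_neighbourhood(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((2, 500))
        C = A.copy()
        smooth_cutpoint(C, A, A, 375)
        np.testing.assert_array_equal(C, A)

    def test_cutpoint_near_edge_rejected(self):
        A = np.zeros((1, 500))
        with pytest.raises(ValueError, match="edge"):
            smooth_cutpoint(A.copy(), A, A, 1)


class TestAugmentBalanced:
    def _pool(self, rng, per_case=3):
        return [
            _rand_window(rng, case=c, wid=f"{c}{i}")
            for c in CASES
            for i in range(per_case)
        ]

    def test_equal_allocation_across_cases(self):
        rng = np.random.default_rng(7)
        out = augment_balanced(self._pool(rng), 2500, DAParams(rng_seed=0))
        assert len(out) == 2500
        counts = {c: sum(w.ppr_case == c for w in out) for c in CASES}
        assert counts == {c: 625 for c in CASES}

    def test_remainder_goes_to_first_cases_in_fixed_order(self):
        rng = np.random.default_rng(8)
        out = augment_balanced(self._pool(rng), 6, DAParams(rng_seed=0))
        counts = {c: sum(w.ppr_case == c for w in out) for c in CASES}
        assert counts == {"onset": 2, "offset": 2, "middle": 1, "whole": 1}

    def test_zero_total_returns_empty(self):
        rng = np.random.default_rng(9)
        assert augment_balanced(self._pool(rng), 0) == []

    def test_single_parent_case_is_named_in_error(self):
        rng = np.random.default_rng(10)
        pool = [_rand_window(rng, case=c, wid=c) for c in CASES]  # 1 per case
        with pytest.raises(ValueError, match="onset"):
            augment_balanced(pool, 4, DAParams(rng_seed=0))

    def test_parents_are_distinct_and_from_the_right_case(self):
        rng = np.random.default_rng(11)
        out = augment_balanced(self._pool(rng), 40, DAParams(rng_seed=1))
        for w in out:
            pa, pb = w.parent_ids
            assert pa != pb
            assert pa.rstrip("0123456789") == w.ppr_case
            assert pb.rstrip("0123456789") == w.ppr_case

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(12)
        pool = self._pool(rng)
        a = augment_balanced(pool, 20, DAParams(rng_seed=5))
        b = augment_balanced(pool, 20, DAParams(rng_seed=5))
        for wa, wb in zip(a, b):
            assert wa.parent_ids == wb.parent_ids
            np.testing.assert_array_equal(wa.data, wb.data)


class TestSpectralSimilarity:
    def test_identical_parents_zero_band_deviation(self):
        rng = np.random.default_rng(13)
        a = _rand_window(rng, wid="a")
        b = make_ppr_window(a.data.copy(), window_id="b")
        child = recombine(a, b)
        rep = spectral_similarity(a, b, child)
        np.testing.assert_allclose(rep.child_power, rep.parent_power, rtol=1e-10)
        assert rep.max_abs_log2_ratio == pytest.approx(0.0, abs=1e-9)

    def test_zero_parents_zero_child_power(self):
        a = make_ppr_window(np.zeros((1, 500)), window_id="a")
        b = make_ppr_window(np.zeros((1, 500)), window_id="b")
        rep = spectral_similarity(a, b, recombine(a, b))
        assert rep.child_power.sum() == 0.0

    def test_sinusoidal_parents_child_power_within_factor_two(self):
        """Oracle: direct periodogram band power of a 10 Hz sinusoid pair."""
        t = np.arange(500) / 500.0
        rng = np.random.default_rng(14)
        a = make_ppr_window(
            np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))[None, :],
            window_id="a",
        )
        b = make_ppr_window(
            np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))[None, :],
            window_id="b",
        )
        child = recombine(a, b)
        # independent oracle for total 1-50 Hz power
        def band_power(x):
            f, p = periodogram(x, fs=500.0)
            return p[(f >= 1) & (f <= 50)].sum()

        parent_mean = 0.5 * (band_power(a.data[0]) + band_power(b.data[0]))
        child_power = band_power(child.data[0])
        assert parent_mean / 2 <= child_power <= parent_mean * 2
        rep = spectral_similarity(a, b, child)
        assert 0.5 <= rep.child_power.sum() / rep.parent_power.sum() <= 2.0
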