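"""Dual-tree transform: reconstruction, linearity, envelopes, shift invariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitdtcwt.dtcwt import (DualTreeCoefficients, detail_envelopes,
                             dtcwt_forward, dtcwt_inverse, envelope,
                             level_coefficient_counts,
                             shift_invariance_metric)


class TestForward:
    def test_zero_input_gives_zero_coefficients(self):
        coeffs = dtcwt_forward(np.zeros(46), levels=5)
        for d in coeffs.details:
            assert np.all(d == 0)
        assert np.all(coeffs.approximation == 0)

    def test_constant_signal_concentrates_in_approximation(self):
        c = 7.5
        coeffs = dtcwt_forward(np.full(32, c), levels=3)
        for d in coeffs.details:
            assert np.max(np.abs(d)) < 1e-8 * abs(c)
        # cascaded lowpass DC gain: sqrt(2) per level, both trees
        expected = c * np.sqrt(2.0) ** 3
        np.testing.assert_allclose(np.real(coeffs.approximation), expected,
                                   atol=1e-8)
        np.testing.assert_allclose(np.imag(coeffs.approximation), expected,
                                   atol=1e-8)

    def test_odd_length_rejected_naming_even_requirement(self):
        with pytest.raises(ValueError, match="even"):
            dtcwt_forward(np.zeros(45), levels=2)

    def test_excessive_depth_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            dtcwt_forward(np.zeros(16), levels=5)

    def test_trees_are_independent_paths(self, filters):
        """Zeroing tree-b filters annihilates only the imaginary branch."""
        from gaitdtcwt.filters import FilterPairSet
        taps = {k: (np.zeros_like(v) if k[1] == "b" and k[2] == "analysis"
                    else v) for k, v in filters.taps.items()}
        crippled = FilterPairSet(taps)
        x = np.sin(np.arange(32) / 3.0)
        coeffs = dtcwt_forward(x, 3, crippled)
        assert all(np.allclose(np.imag(d), 0) for d in coeffs.details)
        assert not any(np.allclose(np.real(d), 0) for d in coeffs.details)


class TestInverse:
    def test_zero_coefficients_reconstruct_zero(self):
        ref = dtcwt_forward(np.zeros(46), levels=5)
        assert np.array_equal(dtcwt_inverse(ref), np.zeros(46))

    def test_impulse_round_trip(self):
        x = np.zeros(64)
        x[10] = 1.0
        xr = dtcwt_inverse(dtcwt_forward(x, levels=3))
        assert abs(xr[10] - 1.0) < 1e-10
        off_peak = np.delete(xr, 10)
        assert np.max(np.abs(off_peak)) < 1e-10

    def test_random_round_trip(self):
        x = np.random.default_rng(5).standard_normal(64)
        xr = dtcwt_inverse(dtcwt_forward(x, levels=4))
        assert np.max(np.abs(x - xr)) < 1e-10

    def test_inconsistent_bookkeeping_rejected(self):
        coeffs = dtcwt_forward(np.ones(32), levels=3)
        broken = DualTreeCoefficients(details=coeffs.details,
                                      approximation=coeffs.approximation,
                                      original_length=32, levels=3,
                                      level_inputs=[32, 16])
        with pytest.raises(ValueError, match="bookkeeping"):
            dtcwt_inverse(broken)

    def test_length_policy_violation_rejected(self):
        coeffs = dtcwt_forward(np.ones(32), levels=3)
        with pytest.raises(ValueError, match="length"):
            DualTreeCoefficients(details=[d[:-1] for d in coeffs.details],
                                 approximation=coeffs.approximation,
                                 original_length=32, levels=3,
                                 level_inputs=coeffs.level_inputs)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(half_n=st.integers(8, 64), levels=st.integers(1, 5),
       seed=st.integers(0, 2 ** 16))
def test_perfect_reconstruction_property(half_n, levels, seed):
    """inverse(forward(x)) == x for any even length and admissible depth."""
    n = 2 * half_n
    if n < 2 ** levels:
        levels = max(1, int(np.log2(n)))
    x = np.random.default_rng(seed).standard_normal(n)
    xr = dtcwt_inverse(dtcwt_forward(x, levels))
    assert np.max(np.abs(x - xr)) < 1e-10


@settings(max_examples=15, derandomize=True, deadline=None)
@given(a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 2 ** 16))
def test_forward_is_linear(a, b, seed):
    rng = np.random.default_rng(seed)
    x, y = rng.standard_normal(48), rng.standard_normal(48)
    ca = dtcwt_forward(a * x + b * y, 3)
    cx, cy = dtcwt_forward(x, 3), dtcwt_forward(y, 3)
    scale = max(1.0, abs(a), abs(b))
    for d_ab, d_x, d_y in zip(ca.details, cx.details, cy.details):
        np.testing.assert_allclose(d_ab, a * d_x + b * d_y,
                                   atol=1e-11 * scale)
    np.testing.assert_allclose(ca.approximation,
                               a * cx.approximation + b * cy.approximation,
                               atol=1e-11 * scale)


def test_coefficient_count_law():
    """The declared even-padding policy predicts every level's count."""
    for n in range(8, 129, 2):
        for levels in range(1, 6):
            if n < 2 ** levels:
                with pytest.raises(ValueError):
                    level_coefficient_counts(n, levels)
                continue
            counts = level_coefficient_counts(n, levels)
            coeffs = dtcwt_forward(np.ones(n), levels)
            assert [len(d) for d in coeffs.details] == counts
            assert len(coeffs.approximation) == counts[-1]


def test_46_frame_level_schedule():
    assert level_coefficient_counts(46, 5) == [23, 12, 6, 3, 2]


class TestEnvelope:
    def test_three_four_five(self):
        np.testing.assert_allclose(envelope([3.0], [4.0]), [5.0])

    def test_zero_imaginary_branch_gives_rectified_real(self):
        re = np.array([-2.0, 1.0, -0.5])
        np.testing.assert_allclose(envelope(re, np.zeros(3)), np.abs(re))

    def test_unit_circle_identity(self):
        t = np.linspace(0, 4 * np.pi, 100)
        np.testing.assert_allclose(envelope(np.cos(t), np.sin(t)), 1.0,
                                   atol=1e-12)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(0)
        re, im = rng.standard_normal(20), rng.standard_normal(20)
        np.testing.assert_allclose(envelope(re, im), envelope(-re, -im))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            envelope([1.0, 2.0], [1.0])


class TestShiftInvariance:
    def test_zero_shift_is_exactly_zero(self):
        x = np.random.default_rng(2).standard_normal(64)
        assert shift_invariance_metric(x, 0, 3) == 0.0

    def test_dual_tree_beats_single_tree_on_tone(self):
        t = np.arange(64)
        tone = np.sin(2 * np.pi * 5 * t / 64)
        dual = shift_invariance_metric(tone, 1, 3)
        single = shift_invariance_metric(tone, 1, 3, mode="single")
        assert dual < single

    def test_white_noise_metric_stays_small(self):
        x = np.random.default_rng(42).standard_normal(64)
        assert shift_invariance_metric(x, 2, 3) < 0.3

    def test_complex_magnitude_smoother_than_rectified_details(self):
        """Near-analyticity: on an off-grid tone the complex coefficient
        magnitudes vary far less than rectified single-tree details."""
        t = np.arange(256)
        tone = np.cos(2 * np.pi * 48 * t / 256)
        coeffs = dtcwt_forward(tone, 4)
        energies = [np.sum(np.abs(d) ** 2) for d in coeffs.details]
        j = int(np.argmax(energies))
        complex_tv = np.sum(np.abs(np.diff(np.abs(coeffs.details[j]))))
        rect_tv = np.sum(np.abs(np.diff(np.abs(np.real(coeffs.details[j])))))
        assert complex_tv < rect_tv

    def test_detail_envelopes_shape_and_mode_validation(self):
        x = np.random.default_rng(1).standard_normal(32)
        e = detail_envelopes(x, 3)
        assert e.shape == (3, 32) and np.all(e >= 0)
        with pytest.raises(ValueError, match="mode"):
            detail_envelopes(x, 3, mode="triple")


def test_single_level_dwt_matches_pywavelets_periodized():
    """Independent oracle: tree-a level-1 coefficient energies match a
    periodized DWT with the same taps in PyWavelets (orthogonality makes
    the subband energy split convention-independent)."""
    pywt = pytest.importorskip("pywt")
    from gaitdtcwt.filters import default_filters
    f = default_filters()
    h0, h1 = f.stage_bank("qshift", "a", "analysis")
    wav = pywt.Wavelet("qshift", filter_bank=[h0[::-1], h1[::-1], h0, h1])
    x = np.random.default_rng(9).standard_normal(64)
    ca, cd = pywt.dwt(x, wav, mode="periodization")
    from gaitdtcwt.dtcwt import _analysis_stage
    lo, hi = _analysis_stage(x, h0, h1)
    assert np.sum(lo ** 2) == pytest.approx(np.sum(ca ** 2), rel=1e-10)
    assert np.sum(hi ** 2) == pytest.approx(np.sum(cd ** 2), rel=1e-10)
    assert np.sum(lo ** 2) + np.sum(hi ** 2) == pytest.approx(np.sum(x ** 2),
                                                              rel=1e-10)
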