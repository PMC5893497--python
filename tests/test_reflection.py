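"""Biased ACF, Levinson-Durbin recursion, step-up/step-down and features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import solve_toeplitz

from eegrc.io_preprocess import FrameSet
from eegrc.reflection import (ACFSequence, ARSpec, DegenerateSignalError,
                              ar_to_reflection, autocorrelation,
                              extract_reflection_features, levinson_reflection,
                              reflection_to_acf, reflection_to_ar,
                              theoretical_acf)

CHANNELS = ("C3", "P3", "O1", "C4", "P4", "O2")

stable_k = st.lists(
    st.floats(-0.95, 0.95).filter(lambda v: abs(v) <= 0.95),
    min_size=1, max_size=6,
)


def frameset_from_array(frames):
    n_frames, n_ch, frame_len = frames.shape
    return FrameSet(
        frames=frames, frame_duration=frame_len / 250.0, frame_shift=0.5,
        fs=250.0, channel_labels=CHANNELS[:n_ch],
        hemisphere_map={ch: "left" for ch in CHANNELS[:n_ch]},
        frame_labels=("M",) * n_frames, session_ids=("s0",) * n_frames,
    )


class TestAutocorrelation:
    @pytest.mark.parametrize("x, max_lag, expected", [
        ([1, 2, 3, 4], 2, (7.5, 5.0, 2.75)),
        ([1, 0, 0, 0], 2, (0.25, 0.0, 0.0)),
        ([0, 0, 0, 0], 2, (0.0, 0.0, 0.0)),
    ])
    def test_matches_direct_sum(self, x, max_lag, expected):
        acf = autocorrelation(np.asarray(x, dtype=float), max_lag)
        np.testing.assert_allclose(acf.values, expected, atol=1e-12)
        assert acf.n_samples == len(x)

    def test_rejects_lag_at_or_beyond_length(self):
        with pytest.raises(ValueError, match="max_lag"):
            autocorrelation(np.ones(4), 4)

    def test_rejects_empty_frame(self):
        with pytest.raises(ValueError, match="empty"):
            autocorrelation(np.empty(0), 1)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=40))
    def test_biased_estimator_bounded_by_lag_zero(self, xs):
        x = np.asarray(xs)
        if np.all(x == 0):
            return
        acf = autocorrelation(x, max_lag=min(6, x.size - 1))
        assert acf.values[0] >= 0
        assert np.all(np.abs(acf.values) <= acf.values[0] + 1e-12)


class TestLevinsonReflection:
    def test_closed_form_first_two_coefficients(self):
        """k1 = r1/r0; k2 = (r2/r0 - k1^2)/(1 - k1^2) — here exactly (0.5, 0)."""
        rset = levinson_reflection(ACFSequence(np.array([1.0, 0.5, 0.25])), 2)
        np.testing.assert_allclose(rset.k, [0.5, 0.0], atol=1e-15)

    def test_white_noise_acf_gives_zero_coefficients(self):
        rset = levinson_reflection(ACFSequence(np.array([1.0, 0.0, 0.0])), 2)
        np.testing.assert_allclose(rset.k, [0.0, 0.0])

    def test_round_trip_through_acf_generation(self):
        acf = reflection_to_acf([0.6, -0.4])
        rset = levinson_reflection(acf, 2)
        np.testing.assert_allclose(rset.k, [0.6, -0.4], atol=1e-12)

    def test_degenerate_predictable_signal_rejected(self):
        # ACF of a perfectly predictable (unit-correlation) signal
        with pytest.raises(DegenerateSignalError):
            levinson_reflection(ACFSequence(np.array([1.0, 1.0, 1.0])), 2)

    def test_zero_power_rejected(self):
        with pytest.raises(DegenerateSignalError):
            levinson_reflection(ACFSequence(np.array([0.0, 0.0, 0.0])), 2)

    @settings(max_examples=100, deadline=None)
    @given(stable_k, st.floats(0.1, 50.0))
    def test_final_predictor_solves_yule_walker(self, ks, r0):
        """Recursion output equals the direct Toeplitz Yule-Walker solve."""
        acf = reflection_to_acf(ks, r0=r0)
        rset = levinson_reflection(acf, len(ks))
        r = acf.values
        direct = solve_toeplitz(r[:-1], r[1:])
        np.testing.assert_allclose(rset.predictor, direct, atol=1e-10)

    @settings(max_examples=100, deadline=None)
    @given(stable_k)
    def test_energy_ladder_monotone_and_bounded(self, ks):
        acf = reflection_to_acf(ks)
        rset = levinson_reflection(acf, len(ks))
        e = rset.residual_energies
        assert np.all(np.diff(e) <= 1e-12)
        assert e[-1] >= -1e-12
        assert e[0] == pytest.approx(acf.values[0])
        np.testing.assert_allclose(
            e[1:], (1 - rset.k ** 2) * e[:-1], rtol=1e-10)
        assert np.all(np.abs(rset.k) < 1)

    @settings(max_examples=60, deadline=None)
    @given(stable_k)
    def test_order_extension_changes_only_last_coefficient(self, ks):
        """Raising the order from p to p+1 leaves k_1..k_p untouched."""
        acf = reflection_to_acf(ks + [0.3])
        low = levinson_reflection(acf, len(ks))
        high = levinson_reflection(acf, len(ks) + 1)
        np.testing.assert_allclose(high.k[:-1], low.k, atol=1e-12)


class TestStepUpStepDown:
    def test_ar1_coefficient_maps_to_single_reflection(self):
        rset = ar_to_reflection(ARSpec(coeffs=[-0.5]))
        np.testing.assert_allclose(rset.k, [0.5])

    def test_unstable_spec_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            ar_to_reflection(ARSpec(coeffs=[-2.0]))

    def test_step_up_rejects_unit_reflection(self):
        with pytest.raises(ValueError, match="k_m"):
            reflection_to_ar([1.0])

    @settings(max_examples=100, deadline=None)
    @given(stable_k)
    def test_step_up_step_down_round_trip(self, ks):
        # error amplification ~ prod 1/(1-k^2): near-unit |k| at order 6
        # costs a few digits, so the bound loosens with max |k|
        spec = reflection_to_ar(ks)
        back = ar_to_reflection(spec)
        tol = 1e-12 if max(abs(k) for k in ks) <= 0.9 else 1e-9
        np.testing.assert_allclose(back.k, ks, atol=tol)

    def test_full_order_predictor_is_negated_ar_coefficients(self):
        spec = reflection_to_ar([0.6, -0.4, 0.2])
        acf = theoretical_acf(spec, 3)
        rset = levinson_reflection(acf, 3)
        np.testing.assert_allclose(rset.predictor, -spec.coeffs, atol=1e-10)


class TestExtractReflectionFeatures:
    def test_feature_dimension_is_coeffs_times_channels(self, rng):
        frames = frameset_from_array(rng.normal(size=(19, 6, 250)))
        feats = extract_reflection_features(frames, n_coeffs=2)
        assert feats.features.shape == (19, 12)
        feats4 = extract_reflection_features(frames, n_coeffs=4)
        assert feats4.features.shape == (19, 24)

    def test_columns_are_channel_major(self, rng):
        frames = frameset_from_array(rng.normal(size=(2, 2, 250)))
        feats = extract_reflection_features(frames, n_coeffs=2)
        assert list(feats.features.columns) == ["C3_k1", "C3_k2",
                                                "P3_k1", "P3_k2"]

    def test_entries_bounded_by_one(self, rng):
        frames = frameset_from_array(rng.normal(size=(19, 6, 250)))
        feats = extract_reflection_features(frames, n_coeffs=4)
        assert np.all(np.abs(feats.values) < 1)

    def test_white_noise_coefficients_small(self, rng):
        """Under whiteness k_hat ~ N(0, 1/N): nearly all within 3/sqrt(N)."""
        n = 250
        frames = frameset_from_array(rng.normal(size=(19, 6, n)))
        vals = extract_reflection_features(frames, n_coeffs=2).values
        assert np.mean(np.abs(vals) <= 3 / np.sqrt(n)) >= 0.99
        assert np.max(np.abs(vals)) < 0.3

    def test_degenerate_frame_identified_in_error(self):
        frames = frameset_from_array(np.zeros((2, 2, 250)))
        with pytest.raises(DegenerateSignalError, match="frame 0, channel C3"):
            extract_reflection_features(frames, 2)

    def test_csv_round_trip(self, tmp_path, rng):
        from eegrc.reflection import FeatureMatrix

        frames = frameset_from_array(rng.normal(size=(5, 2, 250)))
        feats = extract_reflection_features(frames, 2)
        path = tmp_path / "feats.csv"
        feats.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        assert back.labels == feats.labels
        assert back.sessions == feats.sessions
        np.testing.assert_allclose(back.values, feats.values, atol=1e-12)


class TestTheoreticalACF:
    def test_ar1_closed_form(self):
        """AR(1), a1 = -phi: r(m) = sigma^2 phi^m / (1 - phi^2)."""
        phi = 0.5
        acf = theoretical_acf(ARSpec(coeffs=[-phi]), 4)
        expected = phi ** np.arange(5) / (1 - phi ** 2)
        np.testing.assert_allclose(acf.values, expected, atol=1e-12)

    def test_consistent_with_reflection_parameterization(self):
        """theoretical_acf and reflection_to_acf describe the same process."""
        ks = [0.6, -0.4, 0.25]
        spec = reflection_to_ar(ks)
        acf = theoretical_acf(spec, 3)
        scaled = reflection_to_acf(ks, r0=acf.values[0])
        np.testing.assert_allclose(acf.values, scaled.values, atol=1e-10)
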