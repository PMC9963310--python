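"""Montage, filtering, the 32-feature vector, scaling and PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from pprdetect import (
    FEATURE_NAMES,
    AnnotatedRecording,
    apply_average_montage,
    extract_features,
    extract_features_frame,
    fit_scaler_pca,
    preprocess_window,
    transform,
)
from pprdetect.features import FittedTransform, _filters
from tests.conftest import make_ppr_window

FS = 500.0
T = np.arange(500) / FS


def _rec(signal, names=None):
    signal = np.atleast_2d(signal)
    names = names or tuple(f"ch{i}" for i in range(signal.shape[0]))
    return AnnotatedRecording(
        signal=signal, channel_names=names, sampling_rate=FS, intervals=(), recording_id="m"
    )


class TestMontage:
    def test_single_channel_becomes_zero(self):
        out = apply_average_montage(_rec(np.random.default_rng(0).normal(size=(1, 100))))
        np.testing.assert_allclose(out.signal, 0.0)

    def test_two_channels_antisymmetric(self):
        a, b = np.arange(10.0), np.ones(10)
        out = apply_average_montage(_rec(np.vstack([a, b])))
        np.testing.assert_allclose(out.signal[0], (a - b) / 2)
        np.testing.assert_allclose(out.signal[1], (b - a) / 2)

    def test_column_sums_vanish_on_random_matrix(self):
        """Oracle: direct column-mean subtraction."""
        x = np.random.default_rng(1).normal(size=(19, 500))
        out = apply_average_montage(_rec(x))
        assert np.abs(out.signal.sum(axis=0)).max() < 1e-9
        np.testing.assert_allclose(out.signal, x - x.mean(axis=0), atol=1e-12)


class TestPreprocess:
    def test_constant_window_maps_to_zeros(self):
        w = make_ppr_window(np.full((1, 500), 7.3))
        np.testing.assert_allclose(preprocess_window(w), 0.0, atol=1e-12)

    def test_mains_frequency_strongly_attenuated(self):
        """Oracle: the designed filters' magnitude response at 50 Hz."""
        x = np.sin(2 * np.pi * 50 * T)
        y = preprocess_window(x[None, :])
        in_rms = np.sqrt(np.mean(x**2))
        out_rms = np.sqrt(np.mean(y**2))
        assert out_rms < 0.10 * in_rms
        # steady-state design check: the zero-phase cascade's |H|^2 at 50 Hz
        # is essentially zero (edge transients, not the passband, explain the
        # small residual RMS on a 1-second window)
        b, a, sos = _filters(FS)
        _, h_notch = sps.freqz(b, a, worN=[50.0], fs=FS)
        _, h_band = sps.sosfreqz(sos, worN=[50.0], fs=FS)
        assert (np.abs(h_notch[0]) * np.abs(h_band[0])) ** 2 < 1e-3

    def test_passband_tone_preserved(self):
        x = np.sin(2 * np.pi * 10 * T)
        y = preprocess_window(x[None, :])
        ratio = np.sqrt(np.mean(y**2)) / np.sqrt(np.mean(x**2))
        assert 0.8 <= ratio <= 1.2
        b, a, sos = _filters(FS)
        _, h_notch = sps.freqz(b, a, worN=[10.0], fs=FS)
        _, h_band = sps.sosfreqz(sos, worN=[10.0], fs=FS)
        assert (np.abs(h_notch[0]) * np.abs(h_band[0])) ** 2 > 0.9

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_filtering_is_linear(self, scale):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        y1 = preprocess_window((scale * x)[None, :])
        y2 = scale * preprocess_window(x[None, :])
        np.testing.assert_allclose(y1, y2, rtol=1e-8, atol=1e-10)

    def test_unknown_channel_rejected(self):
        w = make_ppr_window(np.zeros((3, 500)), channel_names=("a", "b", "c"))
        with pytest.raises(ValueError, match="unknown channel"):
            preprocess_window(w, channel="Fz")

    def test_fz_selected_from_multichannel_window(self):
        data = np.zeros((3, 500))
        data[1] = np.sin(2 * np.pi * 10 * T)
        w = make_ppr_window(data, channel_names=("O1", "Fz", "O2"))
        y = preprocess_window(w, channel="Fz")
        assert np.sqrt(np.mean(y**2)) > 0.5


class TestFeatures:
    def test_exactly_32_named_features_in_fixed_order(self):
        assert len(FEATURE_NAMES) == 32
        assert len(set(FEATURE_NAMES)) == 32
        v = extract_features(np.random.default_rng(3).normal(size=500))
        assert v.shape == (32,)
        assert np.isfinite(v).all()

    def test_zero_window_has_zero_energy_features(self):
        v = dict(zip(FEATURE_NAMES, extract_features(np.zeros(500))))
        for name in ("std", "total_energy", "abs_energy", "max_amplitude",
                     "kurtosis", "skewness", "rms", "spectral_entropy"):
            assert v[name] == 0.0

    def test_pure_sinusoid_fundamental_and_peak(self):
        """Closed-form oracle: 10 Hz unit tone -> fundamental 10 Hz, max ~1."""
        v = dict(zip(FEATURE_NAMES, extract_features(np.sin(2 * np.pi * 10 * T))))
        assert v["fundamental_frequency"] == pytest.approx(10.0, abs=1.0)
        assert v["max"] == pytest.approx(1.0, abs=0.01)
        assert v["rms"] == pytest.approx(1 / np.sqrt(2), abs=0.01)
        assert v["spectral_centroid"] == pytest.approx(10.0, abs=1.0)
        assert v["median_frequency"] == pytest.approx(10.0, abs=1.0)

    def test_gaussian_noise_moments_within_sampling_bands(self):
        """Oracle: sampling distribution of skewness/kurtosis at n=500.

        Standard errors sqrt(6/n) and sqrt(24/n); assert within 3 SE.
        """
        x = np.random.default_rng(4).standard_normal(500)
        v = dict(zip(FEATURE_NAMES, extract_features(x)))
        assert abs(v["skewness"]) < 3 * np.sqrt(6 / 500)
        assert abs(v["kurtosis"]) < 3 * np.sqrt(24 / 500)

    def test_degenerate_constant_window_is_all_finite(self):
        v = extract_features(np.full(500, 5.0))
        assert np.isfinite(v).all()

    def test_feature_frame_indexes_by_window_id(self, short_recording):
        from pprdetect import slide_windows

        ws = slide_windows(short_recording)[:5]
        frame = extract_features_frame(ws, channel=short_recording.channel_names[0])
        assert frame.shape == (5, 32)
        assert list(frame.columns) == list(FEATURE_NAMES)
        assert list(frame.index) == [w.window_id for w in ws]


class TestScalerPCA:
    def test_two_training_vectors_map_to_unit_interval_endpoints(self):
        X = np.array([[0.0, 10.0, -5.0], [1.0, 20.0, 5.0]])
        t = fit_scaler_pca(X)
        scaled = t.scaler.transform(X)
        np.testing.assert_allclose(sorted(scaled[:, 0]), [0.0, 1.0])
        np.testing.assert_allclose(sorted(scaled[:, 1]), [0.0, 1.0])

    def test_rank_one_variance_gives_single_component(self):
        rng = np.random.default_rng(5)
        direction = rng.normal(size=32)
        X = rng.normal(size=(100, 1)) * direction[None, :]
        t = fit_scaler_pca(X)
        assert t.n_components == 1

    def test_isotropic_features_need_almost_all_components(self):
        """Oracle: eigendecomposition of the sample covariance of scaled data."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(3000, 32))
        t = fit_scaler_pca(X)
        scaled = t.scaler.transform(X)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(scaled.T)))[::-1]
        cum = np.cumsum(eigvals) / eigvals.sum()
        k_oracle = int(np.searchsorted(cum, 0.95)) + 1
        assert t.n_components == k_oracle
        assert t.n_components >= 29  # near-equal variances resist compression

    def test_reconstruction_error_bounded_by_retained_variance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 32)) @ np.diag(np.linspace(0.1, 3, 32))
        t = fit_scaler_pca(X)
        scaled = t.scaler.transform(X)
        Z = t.pca.transform(scaled)
        recon = t.pca.inverse_transform(Z)
        err = np.sum((scaled - scaled.mean(0) - (recon - scaled.mean(0))) ** 2)
        total = np.sum((scaled - scaled.mean(0)) ** 2)
        assert err / total <= 0.05 + 1e-9

    def test_transform_does_not_mutate_fitted_parameters(self):
        rng = np.random.default_rng(8)
        t = fit_scaler_pca(rng.normal(size=(50, 8)))
        mins = t.scaler.data_min_.copy()
        comps = t.pca.components_.copy()
        transform(rng.normal(size=(20, 8)) * 100, t)  # far outside [0, 1]
        np.testing.assert_array_equal(t.scaler.data_min_, mins)
        np.testing.assert_array_equal(t.pca.components_, comps)

    def test_test_vectors_outside_unit_interval_are_not_clipped(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.5, 0.2], [0.1, 0.9]])
        t = fit_scaler_pca(X)
        far = t.scaler.transform(np.array([[10.0, -10.0]]))
        assert far[0, 0] > 1.0 and far[0, 1] < 0.0

    def test_json_roundtrip_preserves_projection(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 12))
        t = fit_scaler_pca(X)
        t2 = FittedTransform.from_json(t.to_json())
        Y = rng.normal(size=(5, 12))
        np.testing.assert_allclose(t.transform(Y), t2.transform(Y), rtol=1e-10)
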