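"""Preprocessing, 32-feature extraction and PCA reduction of EEG windows.

The recognition pipeline works on a single channel (Fz, the frontal midline
electrode most informative for generalized photoparoxysmal discharges).  Each
window is re-referenced (average montage at the recording level), mean-removed,
notch-filtered at 50 Hz (mains) and band-passed to 1-50 Hz, then summarised by
32 features across three domains:

* statistical (7): kurtosis, skewness, standard deviation, maximum, minimum,
  mean absolute deviation, root mean square;
* temporal (8): sum of absolute values, maximum amplitude, sum of absolute
  differences, total energy, absolute energy, area under the curve, histogram
  entropy, lag-1 autocorrelation;
* spectral (17): fundamental frequency, maximum frequency, median frequency,
  maximum power spectrum, spectral centroid / decrease / spread / distance /
  kurtosis / skewness / entropy, positive turning points, roll-off, roll-on,
  spectral variation, power bandwidth, human-range energy.

The exact parameterisation of each feature is frozen here (see the individual
definitions and ``docs/methods.md``); spectra come from a one-sided periodogram
of the 500-sample window.  Feature vectors are min-max scaled to [0, 1] and
projected onto the principal components that explain >= 95% of the training
variance.  Scaler and PCA are fitted on training folds only and applied
unchanged to test data (test values may fall outside [0, 1]; they are not
clipped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats
from sklearn.decomposition import PCA
from sklearn.preprocessing import MinMaxScaler

from .synthetic import AnnotatedRecording
from .windowing import LabeledWindow

__all__ = [
    "FEATURE_NAMES",
    "apply_average_montage",
    "preprocess_window",
    "extract_features",
    "extract_features_frame",
    "FittedTransform",
    "fit_scaler_pca",
    "transform",
]

#: Fixed feature order: 7 statistical, 8 temporal, 17 spectral.
FEATURE_NAMES: tuple[str, ...] = (
    # statistical
    "kurtosis",
    "skewness",
    "std",
    "max",
    "min",
    "mean_abs_deviation",
    "rms",
    # temporal
    "sum_abs_values",
    "max_amplitude",
    "sum_abs_diff",
    "total_energy",
    "abs_energy",
    "area_under_curve",
    "entropy",
    "autocorrelation",
    # spectral
    "fundamental_frequency",
    "maximum_frequency",
    "median_frequency",
    "max_power_spectrum",
    "spectral_centroid",
    "spectral_decrease",
    "spectral_spread",
    "spectral_distance",
    "spectral_kurtosis",
    "spectral_skewness",
    "spectral_entropy",
    "positive_turning_points",
    "roll_off",
    "roll_on",
    "spectral_variation",
    "power_bandwidth",
    "human_range_energy",
)


def apply_average_montage(rec: AnnotatedRecording) -> AnnotatedRecording:
    """Re-reference to the average montage.

    At every sample the cross-channel mean is subtracted from every channel, so
    the output's cross-channel sum is zero at every sample.
    """
    referenced = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return AnnotatedRecording(
        signal=referenced,
        channel_names=rec.channel_names,
        sampling_rate=rec.sampling_rate,
        intervals=rec.intervals,
        recording_id=rec.recording_id,
    )


@lru_cache(maxsize=8)
def _filters(fs: float, notch_hz: float = 50.0, band: tuple[float, float] = (1.0, 50.0)):
    # 2nd-order IIR notch (Q=30) + 4th-order Butterworth band-pass, both applied
    # forward-backward for zero phase.
    b_notch, a_notch = sps.iirnotch(notch_hz, Q=30.0, fs=fs)
    sos_band = sps.butter(4, band, btype="bandpass", output="sos", fs=fs)
    return b_notch, a_notch, sos_band


def preprocess_window(
    w: LabeledWindow | np.ndarray,
    channel: str = "Fz",
    fs: float = 500.0,
    channel_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Select one channel, remove its mean, notch (50 Hz) and band-pass (1-50 Hz).

    Accepts a :class:`LabeledWindow` (channel resolved through its channel
    names) or a raw 1-D/2-D array (with ``channel_names`` for 2-D input).
    Filtering is zero-phase (forward-backward), hence linear in the input.
    Returns a 1-D float array.
    """
    if isinstance(w, LabeledWindow):
        names = w.channel_names
        data = w.data
    else:
        names = tuple(channel_names) if channel_names is not None else None
        data = np.asarray(w, dtype=float)

    if data.ndim == 2:
        if data.shape[0] == 1:
            x = data[0]
        else:
            if names is None:
                raise ValueError("channel names required to select a channel")
            if channel not in names:
                raise ValueError(f"unknown channel {channel!r}; have {names}")
            x = data[tuple(names).index(channel)]
    else:
        x = data
    x = np.asarray(x, dtype=float)

    x = x - x.mean()
    if np.allclose(x, 0.0):
        return x  # constant input: nothing to filter
    b_notch, a_notch, sos_band = _filters(fs)
    x = sps.filtfilt(b_notch, a_notch, x)
    x = sps.sosfiltfilt(sos_band, x)
    return x


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _histogram_entropy(x: np.ndarray, bins: int = 10) -> float:
    """Shannon entropy (nats) of a 10-bin amplitude histogram."""
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _autocorr_lag1(x: np.ndarray) -> float:
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        return 0.0
    return float(np.dot(xc[:-1], xc[1:]) / denom)


def _cum_fraction_freq(f: np.ndarray, weight: np.ndarray, frac: float) -> float:
    """Lowest frequency at which the cumulative weight reaches ``frac`` of its total."""
    total = weight.sum()
    if total <= 0:
        return 0.0
    cum = np.cumsum(weight)
    idx = int(np.searchsorted(cum, frac * total))
    idx = min(idx, len(f) - 1)
    return float(f[idx])


def extract_features(x: np.ndarray, fs: float = 500.0) -> np.ndarray:
    """Compute the 32-feature vector of a preprocessed single-channel window.

    Feature definitions (all frozen; ``P`` is the one-sided periodogram of the
    window, ``M`` the one-sided FFT magnitude, ``f`` their frequencies):

    - ``kurtosis`` / ``skewness``: Fisher (excess) kurtosis and skewness of the
      amplitude distribution; 0 for constant input.
    - ``std`` / ``max`` / ``min`` / ``mean_abs_deviation`` / ``rms``: population
      standard deviation, extrema, mean |x - mean|, root mean square.
    - ``sum_abs_values``: sum |x|; ``max_amplitude``: max |x|;
      ``sum_abs_diff``: sum |x[i+1] - x[i]|.
    - ``total_energy``: sum x^2 / duration (mean power per second);
      ``abs_energy``: sum x^2.
    - ``area_under_curve``: trapezoidal integral of |x| over time.
    - ``entropy``: Shannon entropy (nats) of a 10-bin amplitude histogram.
    - ``autocorrelation``: lag-1 normalized autocorrelation.
    - ``fundamental_frequency``: frequency of the periodogram maximum
      (DC excluded).
    - ``maximum_frequency``: lowest f reaching 95% of cumulative M.
    - ``median_frequency``: lowest f reaching 50% of cumulative P.
    - ``max_power_spectrum``: max P.
    - ``spectral_centroid`` / ``spectral_spread`` / ``spectral_skewness`` /
      ``spectral_kurtosis``: moments of the P-weighted frequency distribution
      (kurtosis as excess).
    - ``spectral_decrease``: sum_{k>=1} (P_k - P_0)/k / sum_{k>=1} P_k.
    - ``spectral_distance``: signed sum of cumulative-P deviations from the
      linear ramp joining its endpoints.
    - ``spectral_entropy``: Shannon entropy of P normalized by log(n_bins),
      in [0, 1].
    - ``positive_turning_points``: number of local maxima of the window
      (first-difference sign changes + -> -).
    - ``roll_off`` / ``roll_on``: lowest f reaching 95% / 5% of cumulative P.
    - ``spectral_variation``: sum |P_{k+1} - P_k| / sum P (flux across
      frequency).
    - ``power_bandwidth``: width of the band where P >= max(P)/2 (first to
      last crossing).
    - ``human_range_energy``: fraction of P in 0.6-2.5 Hz.

    Degenerate inputs (constant windows) return 0 for every feature whose
    definition would divide by a zero quantity.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("window must have at least 2 samples")
    duration = n / fs
    dt = 1.0 / fs

    sd = float(x.std())
    constant = sd == 0.0

    # statistical
    kurt = 0.0 if constant else float(spstats.kurtosis(x, fisher=True, bias=True))
    skew = 0.0 if constant else float(spstats.skew(x, bias=True))
    mad = float(np.abs(x - x.mean()).mean())
    rms = float(np.sqrt(np.mean(x**2)))

    # temporal
    sum_abs = float(np.abs(x).sum())
    max_amp = float(np.abs(x).max())
    sum_abs_diff = float(np.abs(np.diff(x)).sum())
    abs_energy = float(np.sum(x**2))
    total_energy = abs_energy / duration
    auc = float(np.trapezoid(np.abs(x), dx=dt))
    entropy = _histogram_entropy(x)
    autocorr = _autocorr_lag1(x)

    # spectral
    f, P = sps.periodogram(x, fs=fs)
    M = np.abs(np.fft.rfft(x))
    p_total = float(P.sum())
    if p_total <= 0.0:
        spectral = dict.fromkeys(FEATURE_NAMES[15:], 0.0)
        spectral["positive_turning_points"] = _count_peaks(x)
    else:
        p_nodc = P.copy()
        p_nodc[0] = 0.0
        fundamental = float(f[int(np.argmax(p_nodc))])
        maximum_frequency = _cum_fraction_freq(f, M, 0.95)
        median_frequency = _cum_fraction_freq(f, P, 0.50)
        max_power = float(P.max())

        w = P / p_total
        centroid = float(np.sum(f * w))
        spread = float(np.sqrt(np.sum((f - centroid) ** 2 * w)))
        if spread > 0:
            z = (f - centroid) / spread
            s_skew = float(np.sum(z**3 * w))
            s_kurt = float(np.sum(z**4 * w) - 3.0)
        else:
            s_skew = s_kurt = 0.0
        tail = P[1:]
        tail_sum = float(tail.sum())
        decrease = (
            float(np.sum((tail - P[0]) / np.arange(1, len(P))) / tail_sum)
            if tail_sum > 0
            else 0.0
        )
        cum = np.cumsum(P)
        ramp = np.linspace(cum[0], cum[-1], len(cum))
        distance = float(np.sum(cum - ramp))
        pe = w[w > 0]
        s_entropy = float(-(pe * np.log(pe)).sum() / np.log(len(P)))
        roll_off = _cum_fraction_freq(f, P, 0.95)
        roll_on = _cum_fraction_freq(f, P, 0.05)
        variation = float(np.abs(np.diff(P)).sum() / p_total)
        above = np.flatnonzero(P >= 0.5 * P.max())
        bandwidth = float(f[above[-1]] - f[above[0]])
        hre_mask = (f >= 0.6) & (f <= 2.5)
        hre = float(P[hre_mask].sum() / p_total)

        spectral = {
            "fundamental_frequency": fundamental,
            "maximum_frequency": maximum_frequency,
            "median_frequency": median_frequency,
            "max_power_spectrum": max_power,
            "spectral_centroid": centroid,
            "spectral_decrease": decrease,
            "spectral_spread": spread,
            "spectral_distance": distance,
            "spectral_kurtosis": s_kurt,
            "spectral_skewness": s_skew,
            "spectral_entropy": s_entropy,
            "positive_turning_points": _count_peaks(x),
            "roll_off": roll_off,
            "roll_on": roll_on,
            "spectral_variation": variation,
            "power_bandwidth": bandwidth,
            "human_range_energy": hre,
        }

    values = {
        "kurtosis": kurt,
        "skewness": skew,
        "std": sd,
        "max": float(x.max()),
        "min": float(x.min()),
        "mean_abs_deviation": mad,
        "rms": rms,
        "sum_abs_values": sum_abs,
        "max_amplitude": max_amp,
        "sum_abs_diff": sum_abs_diff,
        "total_energy": total_energy,
        "abs_energy": abs_energy,
        "area_under_curve": auc,
        "entropy": entropy,
        "autocorrelation": autocorr,
        **spectral,
    }
    out = np.array([values[name] for name in FEATURE_NAMES])
    return out


def _count_peaks(x: np.ndarray) -> float:
    d = np.diff(x)
    sign = np.sign(d)
    sign = sign[sign != 0]
    if sign.size < 2:
        return 0.0
    return float(np.sum((sign[:-1] > 0) & (sign[1:] < 0)))


def extract_features_frame(
    windows: Iterable[LabeledWindow],
    channel: str = "Fz",
    fs: float = 500.0,
) -> pd.DataFrame:
    """Preprocess and featurize a window collection into a table.

    One row per window (indexed by ``window_id``), one column per feature.
    """
    ids, rows = [], []
    for w in windows:
        filtered = preprocess_window(w, channel=channel, fs=fs)
        rows.append(extract_features(filtered, fs=fs))
        ids.append(w.window_id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="window_id"), columns=list(FEATURE_NAMES))


# ---------------------------------------------------------------------------
# scaling + PCA
# ---------------------------------------------------------------------------

@dataclass
class FittedTransform:
    """Min-max scaler + PCA fitted on a training fold, frozen thereafter.

    Retains the smallest number of principal components whose cumulative
    explained variance reaches the ``variance`` threshold (0.95 by default).
    Zero-variance features scale to 0.  Test vectors are transformed with the
    training parameters unchanged and may fall outside [0, 1].
    """

    scaler: MinMaxScaler
    pca: PCA

    @property
    def n_components(self) -> int:
        return int(self.pca.n_components_)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    def transform(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return self.pca.transform(self.scaler.transform(X))

    def to_json(self) -> str:
        payload = {
            "feature_min": self.scaler.data_min_.tolist(),
            "feature_max": self.scaler.data_max_.tolist(),
            "pca_mean": self.pca.mean_.tolist(),
            "pca_components": self.pca.components_.tolist(),
            "explained_variance": self.pca.explained_variance_.tolist(),
            "explained_variance_ratio": self.pca.explained_variance_ratio_.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "FittedTransform":
        payload = json.loads(text)
        dmin = np.array(payload["feature_min"])
        dmax = np.array(payload["feature_max"])
        scaler = MinMaxScaler()
        n_feat = dmin.size
        scaler.n_features_in_ = n_feat
        scaler.data_min_ = dmin
        scaler.data_max_ = dmax
        scaler.data_range_ = dmax - dmin
        rng_ = scaler.data_range_.copy()
        rng_[rng_ == 0.0] = 1.0
        scaler.scale_ = 1.0 / rng_
        scaler.min_ = -dmin * scaler.scale_
        scaler.n_samples_seen_ = 2
        comps = np.array(payload["pca_components"])
        pca = PCA(n_components=comps.shape[0])
        pca.components_ = comps
        pca.mean_ = np.array(payload["pca_mean"])
        pca.explained_variance_ = np.array(payload["explained_variance"])
        pca.explained_variance_ratio_ = np.array(payload["explained_variance_ratio"])
        pca.whiten = False
        pca.n_components_ = comps.shape[0]
        pca.n_features_in_ = n_feat
        return cls(scaler=scaler, pca=pca)


def fit_scaler_pca(
    train: np.ndarray | pd.DataFrame, variance: float = 0.95
) -> FittedTransform:
    """Fit [0,1] scaling and >= ``variance``-explained PCA on training features."""
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training feature vectors")
    scaler = MinMaxScaler()
    Xs = scaler.fit_transform(X)
    pca = PCA(n_components=variance, svd_solver="full")
    pca.fit(Xs)
    return FittedTransform(scaler=scaler, pca=pca)


def transform(x: np.ndarray | pd.DataFrame, t: FittedTransform) -> np.ndarray:
    """Project feature vectors into the fitted reduced space."""
    return t.transform(x)
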