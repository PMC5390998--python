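"""Surface-EMG preprocessing and sliding-window feature extraction.

The acquisition protocol this module targets records eight perioral/facial
muscles (plus the digastric) at 2048 Hz while the subject holds one of
thirteen static poses for about four seconds.  Raw signals are bandpass
filtered (Butterworth, 15-500 Hz), reduced to amplitude-domain features over
a maximally overlapping sliding window, truncated to exactly three seconds
of feature samples, and finally averaged over time into a single 8-element
feature vector per (pose, repetition) record.  A quadratic augmentation of
that vector (8 linear + 36 product terms = 44 elements) supports nonlinear
regression downstream.

Supported features (``g(j)`` computed over a centred window of N samples):

* ``MAV``  - mean absolute value
* ``RMS``  - root mean square
* ``WL``   - waveform length, the summed absolute first differences
* ``WAMP`` - Willison amplitude, the count of consecutive-sample
  differences whose magnitude reaches a threshold ``s_lim``
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as _signal

__all__ = [
    "MUSCLES",
    "FEATURE_TYPES",
    "WINDOW_GRID_MS",
    "TARGET_FEATURE_SAMPLES",
    "EMGRecording",
    "FeatureSeries",
    "FeatureVector",
    "InvalidBandError",
    "ConfigurationError",
    "WindowError",
    "TruncationError",
    "AlignmentError",
    "bandpass_filter",
    "derive_bipolar",
    "window_samples",
    "extract_feature",
    "truncate_series",
    "average_features",
    "quadratic_terms",
    "augment_quadratic",
]

#: Muscle channel order: zygomaticus major, risorius, orbicularis oris
#: superior/inferior, mentalis, depressor anguli oris, levator labii
#: superioris, digastric.
MUSCLES: tuple[str, ...] = ("ZYG", "RIS", "OOS", "OOI", "MEN", "DAO", "LLS", "DIG")

FEATURE_TYPES: tuple[str, ...] = ("MAV", "RMS", "WL", "WAMP")

#: Window lengths (ms) evaluated in the settings grid.
WINDOW_GRID_MS: tuple[int, ...] = (50, 100, 150, 200, 250, 300)

#: Three seconds of feature samples at 2048 Hz, both endpoints included.
TARGET_FEATURE_SAMPLES: int = 6145


class InvalidBandError(ValueError):
    """Bandpass cut-offs incompatible with the sampling rate."""


class ConfigurationError(ValueError):
    """Electrode configuration / pairing problem."""


class WindowError(ValueError):
    """Sliding window longer than the available record."""


class TruncationError(ValueError):
    """Feature series shorter than the requested truncation length."""


class AlignmentError(ValueError):
    """Channel lengths or counts do not line up."""


@dataclass
class EMGRecording:
    """Multi-channel sEMG record for one (pose, repetition).

    ``samples`` is channels x time in the stored amplitude unit (mV).
    Unipolar recordings may carry 16 channels (two electrodes per muscle)
    before bipolar derivation; the analysis pipeline always works on 8.
    Pose 0 is the rest pose.
    """

    samples: np.ndarray
    fs: float
    configuration: str = "unipolar"
    channel_labels: tuple[str, ...] = MUSCLES
    pose_id: int = 0
    repetition_id: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise AlignmentError("samples must be a channels x time array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.configuration not in ("unipolar", "bipolar"):
            raise ConfigurationError(f"unknown configuration {self.configuration!r}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise AlignmentError("channel_labels must match the channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class FeatureSeries:
    """Per-channel feature time series ``g(j)`` from a sliding window."""

    values: np.ndarray  # channels x (n - p + 1)
    feature_type: str
    window_ms: float
    window_samples: int
    s_lim: float | None = None
    channel_labels: tuple[str, ...] = MUSCLES
    pose_id: int = 0
    repetition_id: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise AlignmentError("values must be channels x time")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureVector:
    """Time-averaged feature vector and its quadratic augmentation."""

    gbar: np.ndarray  # 8 elements, order fixed by channel_labels
    gbar_aug: np.ndarray = field(default=None)  # type: ignore[assignment]
    channel_labels: tuple[str, ...] = MUSCLES
    pose_id: int = 0
    repetition_id: int = 1

    def __post_init__(self) -> None:
        self.gbar = np.asarray(self.gbar, dtype=float)
        if self.gbar.shape != (8,):
            raise AlignmentError("gbar must have exactly 8 elements")
        if self.gbar_aug is None:
            self.gbar_aug = augment_quadratic(self.gbar)
        self.gbar_aug = np.asarray(self.gbar_aug, dtype=float)
        if self.gbar_aug.shape != (44,):
            raise AlignmentError("gbar_aug must have exactly 44 elements")


def bandpass_filter(
    recording: EMGRecording,
    low: float = 15.0,
    high: float = 500.0,
    order: int = 4,
) -> EMGRecording:
    """Zero-phase Butterworth bandpass (defaults 15-500 Hz, order 4).

    No mains-notch filter is applied.  ``order`` is the design order passed
    to the Butterworth prototype; a bandpass of design order 4 has 8 poles.
    """
    if not 0 < low < high:
        raise InvalidBandError("need 0 < low < high")
    if high >= recording.fs / 2:
        raise InvalidBandError(
            f"high cut-off {high} Hz must be below Nyquist ({recording.fs / 2} Hz)"
        )
    sos = _signal.butter(order, [low, high], btype="band", fs=recording.fs, output="sos")
    filtered = _signal.sosfiltfilt(sos, recording.samples, axis=-1)
    return replace(recording, samples=filtered)


def derive_bipolar(
    unipolar: EMGRecording,
    pairing: Sequence[tuple[int, int]] | None = None,
) -> EMGRecording:
    """Derive an 8-channel bipolar recording from paired unipolar electrodes.

    Each output channel is the sample-wise difference *second electrode minus
    first* of its pair.  With 16 input channels the default pairing is
    consecutive: muscle m uses electrodes (2m, 2m+1).  An 8-channel input is
    treated as already paired and only relabelled.
    """
    if unipolar.configuration != "unipolar":
        raise ConfigurationError("input recording is not unipolar")
    if unipolar.n_channels == 8 and pairing is None:
        return replace(unipolar, configuration="bipolar")
    if pairing is None:
        if unipolar.n_channels != 16:
            raise ConfigurationError(
                "default pairing needs 16 channels (2 electrodes per muscle); "
                f"got {unipolar.n_channels}"
            )
        pairing = [(2 * m, 2 * m + 1) for m in range(8)]
    if len(pairing) != 8:
        raise ConfigurationError("pairing must define exactly 8 electrode pairs")
    out = np.empty((8, unipolar.n_samples))
    for m, (first, second) in enumerate(pairing):
        try:
            out[m] = unipolar.samples[second] - unipolar.samples[first]
        except IndexError as exc:  # pragma: no cover - message matters, not path
            raise ConfigurationError(f"pair ({first}, {second}) out of range") from exc
    labels = tuple(lbl.split("_")[0] for lbl in unipolar.channel_labels[::2]) \
        if unipolar.n_channels == 16 else MUSCLES
    return EMGRecording(
        samples=out,
        fs=unipolar.fs,
        configuration="bipolar",
        channel_labels=labels,
        pose_id=unipolar.pose_id,
        repetition_id=unipolar.repetition_id,
    )


def window_samples(window_ms: float, fs: float) -> int:
    """Window length in samples, rounded to the nearest odd integer.

    Odd N keeps the centred window index j +/- (N-1)/2 integral.  Exact
    ties between the two neighbouring odd integers round up.
    """
    n = window_ms * fs / 1000.0
    lower = int(np.floor(n))
    lo = lower if lower % 2 == 1 else lower - 1
    hi = lo + 2
    N = lo if (n - lo) < (hi - n) else hi
    if N < 1:
        raise WindowError("window shorter than one sample")
    return N


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sums over all full windows of length ``w`` along the last axis."""
    cs = np.cumsum(x, axis=-1, dtype=np.float64)
    out = cs[..., w - 1:].copy()
    out[..., 1:] -= cs[..., :-w]
    return out


def extract_feature(
    recording: EMGRecording,
    feature_type: str,
    window_ms: float,
    s_lim: float | None = None,
) -> FeatureSeries:
    """Sliding-window feature series with maximum (all-but-one sample) overlap.

    Only full windows are evaluated: a record of n samples and a window of
    p samples yields n - p + 1 feature samples.  ``s_lim`` (same amplitude
    unit as the stored signal) is required for WAMP and ignored otherwise.
    """
    if feature_type not in FEATURE_TYPES:
        raise ValueError(f"unknown feature type {feature_type!r}")
    if feature_type == "WAMP" and s_lim is None:
        raise ValueError("WAMP requires the threshold s_lim")
    N = window_samples(window_ms, recording.fs)
    s = recording.samples
    if N > s.shape[1]:
        raise WindowError(
            f"window of {N} samples longer than record of {s.shape[1]}"
        )
    if feature_type == "MAV":
        values = _sliding_sum(np.abs(s), N) / N
    elif feature_type == "RMS":
        values = np.sqrt(_sliding_sum(np.square(s), N) / N)
    else:
        diffs = np.abs(np.diff(s, axis=-1))
        if feature_type == "WL":
            values = _sliding_sum(diffs, N - 1)
        else:  # WAMP: count of |s(i+1)-s(i)| >= s_lim within the window
            values = np.rint(_sliding_sum((diffs >= s_lim).astype(np.float64), N - 1))
    return FeatureSeries(
        values=values,
        feature_type=feature_type,
        window_ms=window_ms,
        window_samples=N,
        s_lim=s_lim if feature_type == "WAMP" else None,
        channel_labels=recording.channel_labels,
        pose_id=recording.pose_id,
        repetition_id=recording.repetition_id,
    )


def truncate_series(
    series: FeatureSeries, target_samples: int = TARGET_FEATURE_SAMPLES
) -> FeatureSeries:
    """Keep the first ``target_samples`` feature samples (default 6145 = 3 s
    at 2048 Hz) so every record contributes an equal-length feature set."""
    if series.n_samples < target_samples:
        raise TruncationError(
            f"series has {series.n_samples} samples; {target_samples} required"
        )
    if series.n_samples == target_samples:
        return series
    return replace(series, values=series.values[:, :target_samples])


def average_features(series: FeatureSeries) -> FeatureVector:
    """Average an 8-channel feature series over time into one vector."""
    if series.values.shape[0] != 8:
        raise AlignmentError(
            f"expected 8 channels, got {series.values.shape[0]}"
        )
    gbar = series.values.mean(axis=1)
    return FeatureVector(
        gbar=gbar,
        channel_labels=series.channel_labels,
        pose_id=series.pose_id,
        repetition_id=series.repetition_id,
    )


def quadratic_terms(v: np.ndarray) -> np.ndarray:
    """All k(k+1)/2 distinct products v_i * v_j with i <= j, squares included.

    Order: (0,0), (0,1), ..., (0,k-1), (1,1), (1,2), ..., (k-1,k-1).
    """
    v = np.asarray(v, dtype=float)
    i, j = np.triu_indices(v.size)
    return v[i] * v[j]


def augment_quadratic(gbar: np.ndarray) -> np.ndarray:
    """44-element augmentation: 8 linear terms followed by the 36 quadratic
    products in the documented (row-major upper-triangular) order."""
    gbar = np.asarray(gbar, dtype=float)
    if gbar.shape != (8,):
        raise AlignmentError("expected an 8-element feature vector")
    if not np.all(np.isfinite(gbar)):
        raise ValueError("feature vector contains non-finite values")
    return np.concatenate([gbar, quadratic_terms(gbar)])
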