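"""Sensor-space cleaning: bandpass + resampling, bad-channel interpolation,
average re-referencing, and sensor-by-sensor epoch rejection.

The filter is a zero-phase forward-backward 4th-order Butterworth bandpass
(0.3-50 Hz), chosen to avoid latency shifts that would bias onset
statistics downstream; resampling is polyphase at the rational ratio of the
target and native rates (420/500 = 21/25, i.e. 7 samples per 60 Hz video
frame).  Per-channel artifact thresholds are 5 robust standard deviations
(1.4826 * MAD) clamped into [30, 80] µV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "RawRecording",
    "ArtifactMask",
    "bandpass_and_resample",
    "detect_and_interpolate_bad_channels",
    "rereference_average",
    "reject_epochs",
    "channel_thresholds",
]

THRESHOLD_BOUNDS_UV = (30.0, 80.0)


@dataclass
class RawRecording:
    """Continuous multichannel EEG in µV with channel layout metadata."""

    data: np.ndarray               # (n_channels, n_samples)
    sampling_rate: float
    ch_names: list
    positions: np.ndarray          # (n_channels, 2)
    reference: str = "Cz"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape[0] != self.data.shape[0]:
            raise ValueError("one 2-D position required per channel")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("one name required per channel")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ArtifactMask:
    """Excluded (channel, 1-s epoch) cells and the thresholds that made them."""

    mask: np.ndarray               # (n_channels, n_epochs) bool, True = excluded
    thresholds: np.ndarray         # (n_channels,) µV
    epoch_len_s: float = 1.0


def bandpass_and_resample(
    raw: RawRecording,
    low: float = 0.3,
    high: float = 50.0,
    target_rate: float = 420.0,
) -> RawRecording:
    """Zero-phase bandpass then polyphase resample to ``target_rate``."""
    nyq = raw.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    if target_rate > raw.sampling_rate:
        raise ValueError("target_rate above the input rate (no upsampling)")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=raw.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, raw.data, axis=-1)
    ratio = Fraction(target_rate / raw.sampling_rate).limit_denominator(1000)
    resampled = signal.resample_poly(filtered, ratio.numerator, ratio.denominator, axis=-1)
    return replace(raw, data=resampled, sampling_rate=target_rate)


def channel_thresholds(data: np.ndarray, robust_k: float = 5.0) -> np.ndarray:
    """Per-channel amplitude threshold: robust_k robust SDs, clamped to 30-80 µV."""
    mad = np.median(np.abs(data - np.median(data, axis=-1, keepdims=True)), axis=-1)
    thr = robust_k * 1.4826 * mad
    return np.clip(thr, *THRESHOLD_BOUNDS_UV)


def detect_and_interpolate_bad_channels(
    raw: RawRecording,
    bad_fraction: float = 0.15,
    robust_k: float = 5.0,
    n_neighbors: int = 6,
    max_bad_fraction: float = 0.25,
):
    """Flag consistently noisy channels and replace them by the unweighted
    mean of their ``n_neighbors`` nearest good channels (Euclidean layout
    distance).

    A channel is bad when more than ``bad_fraction`` of its samples exceed
    its clamped robust threshold in absolute value.  More than
    ``max_bad_fraction`` of channels bad is treated as unusable data.
    Returns (cleaned RawRecording, list of bad channel names).
    """
    if raw.n_channels < n_neighbors + 1:
        raise ValueError(f"need at least {n_neighbors + 1} channels")
    thr = channel_thresholds(raw.data, robust_k)
    above = (np.abs(raw.data) > thr[:, None]).mean(axis=-1)
    bad = np.flatnonzero(above > bad_fraction)
    if len(bad) > max_bad_fraction * raw.n_channels:
        raise ValueError(
            f"{len(bad)} of {raw.n_channels} channels flagged bad; data unusable"
        )
    data = raw.data.copy()
    good = np.setdiff1d(np.arange(raw.n_channels), bad)
    for ch in bad:
        dist = np.linalg.norm(raw.positions[good] - raw.positions[ch], axis=1)
        neighbors = good[np.argsort(dist)[:n_neighbors]]
        data[ch] = raw.data[neighbors].mean(axis=0)
    return replace(raw, data=data), [raw.ch_names[i] for i in bad]


def rereference_average(raw: RawRecording) -> RawRecording:
    """Re-reference to the instantaneous average of all channels."""
    if raw.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = raw.data - raw.data.mean(axis=0, keepdims=True)
    return replace(raw, data=data, reference="average")


def reject_epochs(
    raw: RawRecording,
    epoch_len: float = 1.0,
    frac: float = 0.10,
    thresholds: np.ndarray | None = None,
) -> ArtifactMask:
    """Mark (channel, epoch) cells where strictly more than ``frac`` of the
    epoch's samples exceed the channel threshold in absolute value.

    The epoch grid tiles the recording in ``epoch_len`` chunks; a trailing
    partial epoch is dropped from the grid.
    """
    n_per = round(epoch_len * raw.sampling_rate)
    if raw.n_samples < n_per:
        raise ValueError("recording shorter than one epoch")
    if thresholds is None:
        thresholds = channel_thresholds(raw.data)
    else:
        thresholds = np.asarray(thresholds, dtype=float)
        lo, hi = THRESHOLD_BOUNDS_UV
        if np.any(thresholds < lo) or np.any(thresholds > hi):
            raise ValueError(f"thresholds must lie within [{lo}, {hi}] µV")
    n_epochs = raw.n_samples // n_per
    chunks = raw.data[:, : n_epochs * n_per].reshape(raw.n_channels, n_epochs, n_per)
    over = (np.abs(chunks) > thresholds[:, None, None]).mean(axis=-1)
    return ArtifactMask(mask=over > frac, thresholds=thresholds, epoch_len_s=epoch_len)


def mask_to_samples(mask: ArtifactMask, sampling_rate: float, n_samples: int) -> np.ndarray:
    """Expand an epoch-level mask to a per-sample boolean (channels, samples)."""
    n_per = round(mask.epoch_len_s * sampling_rate)
    out = np.zeros((mask.mask.shape[0], n_samples), dtype=bool)
    for e in range(mask.mask.shape[1]):
        sl = slice(e * n_per, min((e + 1) * n_per, n_samples))
        out[:, sl] = mask.mask[:, e][:, None]
    return out
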