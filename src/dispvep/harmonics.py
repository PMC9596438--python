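"""Fourier-transform-as-filter harmonic decomposition of cycle-aligned epochs.

Steady-state responses concentrate at integer multiples of the stimulus
fundamentals: the disparity modulation F1 (1.4 Hz) and the dot-update rate
F2 (20 Hz).  Filtering keeps a named set of harmonic bins of a whole-epoch
DFT and inverse-transforms:

* ``nf1_clean`` — all k·F1 up to fmax that do not coincide with any m·F2
  (with F1 = 1.4 and F2 = 20 the smallest common multiple is 140 Hz, so
  below a 50 Hz fmax nothing is excluded);
* ``nf2``      — all m·F2 up to fmax (20 and 40 Hz at the defaults);
* ``odd``/``even`` — odd/even k·F1 only.  Odd-harmonic reconstructions are
  exactly half-F1-period antisymmetric (sustained activity), even ones
  symmetric (transient activity).

DC is always removed.  Bin matching uses exact rational arithmetic on the
frequencies, never floating-point equality.  Epochs must contain an integer
number of F1 cycles; no tapering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "FilterSpec",
    "HarmonicSpectrum",
    "harmonic_bins",
    "apply_spectral_filter",
    "epoch_spectrum",
    "cycle_average",
]

_KINDS = ("nf1_clean", "nf2", "odd", "even")


def _frac(x) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(str(x))


@dataclass(frozen=True)
class FilterSpec:
    """A named harmonic keep-set."""

    kind: str
    f1: float = 1.4
    f2: float = 20.0
    fmax: float = 50.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("f1 and f2 must be positive")
        if self.fmax <= 0:
            raise ValueError("fmax must be positive")


@dataclass
class HarmonicSpectrum:
    """Complex one-sided DFT coefficients of a cycle-aligned epoch."""

    coefficients: np.ndarray   # rfft output, last axis = frequency bins
    frequencies: np.ndarray    # Hz, bin resolution = 1/epoch_duration
    n_samples: int
    sampling_rate: float


def harmonic_bins(spec: FilterSpec) -> list[float]:
    """Ordered kept frequencies (Hz) for a filter spec.

    Raises if the keep-set is empty (fmax below the first harmonic).
    """
    f1, f2, fmax = _frac(spec.f1), _frac(spec.f2), _frac(spec.fmax)
    nf2 = set()
    m = 1
    while m * f2 <= fmax:
        nf2.add(m * f2)
        m += 1
    out: list[Fraction] = []
    if spec.kind == "nf2":
        out = sorted(nf2)
    else:
        k = 1
        while k * f1 <= fmax:
            f = k * f1
            keep = {
                "nf1_clean": f not in nf2,
                "odd": k % 2 == 1,
                "even": k % 2 == 0,
            }[spec.kind]
            if keep:
                out.append(f)
            k += 1
    if not out:
        raise ValueError(f"empty harmonic set for {spec}")
    return [float(f) for f in out]


def _kept_bin_indices(spec: FilterSpec, n_samples: int, fs: float) -> np.ndarray:
    """DFT bin indices of the kept harmonics.  Each kept frequency must fall
    exactly on a bin, i.e. f * N / fs must be an integer."""
    duration = Fraction(n_samples) / _frac(fs)
    cycles = _frac(spec.f1) * duration
    if cycles.denominator != 1:
        raise ValueError(
            "epoch must contain an integer number of F1 cycles "
            f"(got {float(cycles):g})"
        )
    idx = []
    for f in harmonic_bins(spec):
        b = _frac(f) * duration
        if b.denominator != 1:
            raise ValueError(f"harmonic {f} Hz does not fall on a DFT bin")
        b = int(b)
        if b <= n_samples // 2:
            idx.append(b)
    return np.asarray(idx, dtype=int)


def epoch_spectrum(epoch: np.ndarray, fs: float, f1: float = 1.4) -> HarmonicSpectrum:
    """One-sided DFT of a cycle-aligned epoch (any leading axes)."""
    epoch = np.asarray(epoch, dtype=float)
    n = epoch.shape[-1]
    cycles = _frac(f1) * Fraction(n) / _frac(fs)
    if cycles.denominator != 1:
        raise ValueError("epoch must contain an integer number of F1 cycles")
    return HarmonicSpectrum(
        coefficients=np.fft.rfft(epoch, axis=-1),
        frequencies=np.fft.rfftfreq(n, d=1.0 / fs),
        n_samples=n,
        sampling_rate=fs,
    )


def apply_spectral_filter(epoch: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Keep only the spec's harmonic bins of the epoch's DFT and invert.

    Operates along the last axis; DC and all non-kept bins (and their
    conjugate partners, implicitly through the one-sided transform) are
    zeroed, so the output is real, mean-free, and the same length as the
    input.  A projection: applying the same filter twice is a no-op.
    """
    epoch = np.asarray(epoch, dtype=float)
    n = epoch.shape[-1]
    keep = _kept_bin_indices(spec, n, fs)
    coefs = np.fft.rfft(epoch, axis=-1)
    mask = np.zeros(coefs.shape[-1], dtype=bool)
    mask[keep] = True
    coefs = np.where(mask, coefs, 0.0)
    return np.fft.irfft(coefs, n=n, axis=-1)


def cycle_average(
    waveforms: np.ndarray,
    f1: float,
    fs: float,
    unit_axis: int | None = None,
):
    """Fold cycle-aligned waveforms into one mean stimulus cycle.

    ``waveforms`` has time on the last axis (an integer number of F1
    cycles).  Cycles are averaged within each unit; if ``unit_axis`` is
    given (e.g. subjects at the group level), the mean and the between-unit
    SEM across that axis are returned as (mean_cycle, sem_cycle); otherwise
    (cycles_mean, None).
    """
    waveforms = np.asarray(waveforms, dtype=float)
    period = _frac(fs) / _frac(f1)
    if period.denominator != 1:
        raise ValueError("fs must be an integer multiple of f1")
    period = int(period)
    n = waveforms.shape[-1]
    if n % period:
        raise ValueError("waveform length must be a multiple of the cycle length")
    folded = waveforms.reshape(*waveforms.shape[:-1], n // period, period).mean(axis=-2)
    if unit_axis is None:
        return folded, None
    n_units = folded.shape[unit_axis]
    mean = folded.mean(axis=unit_axis)
    if n_units > 1:
        sem = folded.std(axis=unit_axis, ddof=1) / np.sqrt(n_units)
    else:
        sem = np.zeros_like(mean)
    return mean, sem
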