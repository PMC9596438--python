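"""Readers and writers: HDF5 trial containers and standard EEG formats."""

from __future__ import annotations

import os

import h5py
import numpy as np

from .preprocess import RawRecording
from .synth import TrialSet

__all__ = [
    "save_trialset",
    "load_trialset",
    "load_recording",
    "trialset_trial_to_raw",
    "raw_to_fif",
    "raw_from_mne",
]


def save_trialset(ts: TrialSet, path: str, **attrs) -> None:
    """Write a TrialSet to an HDF5 container with its metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data, compression="gzip", compression_opts=1)
        f.create_dataset("channel_positions", data=ts.channel_positions)
        if ts.mask is not None:
            f.create_dataset("mask", data=ts.mask)
        f.attrs["sampling_rate"] = ts.sampling_rate
        f.attrs["f1"] = ts.f1
        f.attrs["f2"] = ts.f2
        f.attrs["conditions"] = [c.encode() for c in ts.conditions]
        for k, v in attrs.items():
            f.attrs[k] = v


def load_trialset(path: str) -> TrialSet:
    with h5py.File(path, "r") as f:
        conditions = tuple(
            c.decode() if isinstance(c, bytes) else str(c)
            for c in f.attrs["conditions"]
        )
        return TrialSet(
            data=f["data"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            f1=float(f.attrs["f1"]),
            f2=float(f.attrs["f2"]),
            conditions=conditions,
            channel_positions=f["channel_positions"][()],
            mask=f["mask"][()] if "mask" in f else None,
        )


def _import_mne():
    import mne  # local import: heavy
    mne.set_log_level("ERROR")
    return mne


def raw_from_mne(raw) -> RawRecording:
    """Convert an mne Raw to the internal µV container."""
    data = raw.get_data() * 1e6  # volts -> µV
    pos = np.array([ch["loc"][:2] for ch in raw.info["chs"]])
    if not np.all(np.isfinite(pos)):
        raise ValueError("recording is missing channel positions (montage)")
    return RawRecording(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        positions=pos,
    )


def load_recording(path: str, fmt: str | None = None) -> RawRecording:
    """Read an EDF / BrainVision / FIF recording into µV.

    ``fmt`` may be "edf", "brainvision" or "fif"; inferred from the file
    extension when omitted.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"recording not found: {path}")
    mne = _import_mne()
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {".edf": "edf", ".vhdr": "brainvision", ".fif": "fif"}.get(ext)
    readers = {
        "edf": mne.io.read_raw_edf,
        "brainvision": mne.io.read_raw_brainvision,
        "fif": mne.io.read_raw_fif,
    }
    if fmt not in readers:
        raise ValueError(f"unknown recording format: {fmt!r} (stage: load_recording)")
    raw = readers[fmt](path, preload=True, verbose="ERROR")
    return raw_from_mne(raw)


def trialset_trial_to_raw(ts: TrialSet, subject: int = 0, condition: int = 0, trial: int = 0):
    """One trial as an mne RawArray (volts, eeg channels, with positions)."""
    mne = _import_mne()
    data = ts.data[subject, condition, trial] / 1e6  # µV -> volts
    n_ch = data.shape[0]
    names = [f"E{i + 1}" for i in range(n_ch)]
    info = mne.create_info(names, ts.sampling_rate, ch_types="eeg")
    raw = mne.io.RawArray(data, info, verbose="ERROR")
    for i, ch in enumerate(raw.info["chs"]):
        ch["loc"][:2] = ts.channel_positions[i]
    return raw


def raw_to_fif(raw, path: str) -> None:
    if not path.endswith("raw.fif"):
        raise ValueError("mne requires FIF filenames ending in 'raw.fif'")
    raw.save(path, overwrite=True, verbose="ERROR")
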