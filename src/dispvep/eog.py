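"""Electro-oculogram control analysis.

Quantifies eye-movement variability from bipolar HEOG/VEOG derivations and
asks whether attention-related differences in eye movements can explain
attention effects in the VEP.  The key statistic is the modulation index

    MI = |var_A - var_B| / (var_A + var_B),

computed per subject once for the EOG trace variance between attention
conditions and once for the VEP response, then correlated across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ModulationIndex",
    "derive_bipolar_eog",
    "trace_variability",
    "modulation_index",
    "correlate_indices",
    "attention_modulation_indices",
]


@dataclass(frozen=True)
class ModulationIndex:
    value: float
    var_a: float
    var_b: float
    kind: str = "eye_movement"  # or "vep_attention"


def derive_bipolar_eog(data: np.ndarray, ch_names: list, pair_map: dict) -> dict:
    """Bipolar EOG traces from named electrode pairs.

    ``data`` is (..., n_channels, n_samples); ``pair_map`` maps a derivation
    name (e.g. "heog") to a (channel_name_plus, channel_name_minus) pair.
    Returns {name: (..., n_samples)} difference traces; trial structure is
    preserved in the leading axes.
    """
    out = {}
    for name, (plus, minus) in pair_map.items():
        for ch in (plus, minus):
            if ch not in ch_names:
                raise KeyError(f"electrode {ch!r} not in montage")
        i, j = ch_names.index(plus), ch_names.index(minus)
        out[name] = data[..., i, :] - data[..., j, :]
    return out


def trace_variability(trace: np.ndarray) -> float:
    """Sample standard deviation over time of a subject's mean trace (µV)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must have at least 2 samples")
    return float(trace.std(ddof=1))


def modulation_index(var_a: float, var_b: float, kind: str = "eye_movement") -> ModulationIndex:
    """|a - b| / (a + b) for two nonnegative variances (not both zero)."""
    if var_a < 0 or var_b < 0:
        raise ValueError("variances must be nonnegative")
    total = var_a + var_b
    if total == 0:
        raise ValueError("both variances are zero; index undefined")
    return ModulationIndex(abs(var_a - var_b) / total, var_a, var_b, kind)


def correlate_indices(eye_indices, vep_indices):
    """Pearson correlation of paired per-subject indices; returns (r, p)."""
    x = np.asarray(eye_indices, dtype=float)
    y = np.asarray(vep_indices, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("indices must be paired 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 subjects")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance indices")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def attention_modulation_indices(traces_a: np.ndarray, traces_b: np.ndarray,
                                 kind: str = "eye_movement") -> np.ndarray:
    """Per-subject modulation indices from condition-mean traces.

    Inputs are (n_subjects, n_trials, n_samples) single-trial traces (or
    (n_subjects, n_samples) ready-made means) for the two attention
    conditions; variance is computed on each subject's mean trace.
    """
    a = np.asarray(traces_a, dtype=float)
    b = np.asarray(traces_b, dtype=float)
    if a.ndim == 3:
        a = a.mean(axis=1)
    if b.ndim == 3:
        b = b.mean(axis=1)
    out = np.empty(a.shape[0])
    for s in range(a.shape[0]):
        va = trace_variability(a[s]) ** 2
        vb = trace_variability(b[s]) ** 2
        out[s] = modulation_index(va, vb, kind).value
    return out
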