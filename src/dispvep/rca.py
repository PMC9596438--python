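"""Reliable Components Analysis (RCA).

RCA finds spatial filters w maximizing the ratio of across-trial to
within-trial covariance,

    rho(w) = (w' C_across w) / (w' C_within w),

so the first component (RC1) is the electrode combination whose time course
is most reproducible across repeated presentations of the same stimulus.
The optimum is the generalized eigenproblem C_across w = lambda C_within w,
solved on the rank-K principal subspace of C_within for regularization.
Weights are mapped back to interpretable scalp patterns through the forward
model A = C W (W' C W)^-1.

Training pools trials across task conditions but within a disparity
stimulus type (plane and grating get separate models); weights are learned
on nF1-clean filtered data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .harmonics import FilterSpec, apply_spectral_filter
from .synth import TrialSet

__all__ = [
    "RCModel",
    "trial_covariances",
    "fit_rca",
    "forward_model",
    "project",
    "fit_rca_trialset",
    "project_trialset",
]


@dataclass
class RCModel:
    """Fitted RCA weights, reliability coefficients and forward model."""

    weights: np.ndarray        # (n_channels, n_components)
    reliabilities: np.ndarray  # eigenvalues, nonincreasing
    forward: np.ndarray        # (n_channels, n_components)
    rank: int
    training: dict | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if np.any(np.diff(self.reliabilities) > 1e-12):
            raise ValueError("reliabilities must be nonincreasing")
        if self.forward.shape != self.weights.shape:
            raise ValueError("forward model must match weight shape")


def _demean(trials: np.ndarray) -> np.ndarray:
    return trials - trials.mean(axis=-1, keepdims=True)


def trial_covariances(trials: np.ndarray, mask: np.ndarray | None = None):
    """Within- and across-trial channel covariance matrices.

    ``trials`` is (n_trials, n_channels, n_samples); ``mask`` (optional) is
    a boolean of the same shape or (n_trials, n_samples), True = excluded.
    Masked samples are handled pairwise-complete — a timepoint enters the
    cross term of a trial pair only if valid in both.

    C_within is the average over trials of each trial's covariance;
    C_across is the symmetrized average of cross-covariances over all
    ordered trial pairs i != j at identical timepoints.  For identical
    trials the two are equal.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3:
        raise ValueError("trials must be (n_trials, n_channels, n_samples)")
    n_trials, n_ch, n_samp = trials.shape
    if n_trials < 2:
        raise ValueError("at least 2 trials are required")

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape == (n_trials, n_samp):
            mask = np.broadcast_to(mask[:, None, :], trials.shape)
        if mask.shape != trials.shape:
            raise ValueError("mask shape incompatible with trials")
        valid = ~mask.any(axis=1)  # (n_trials, n_samples): a sample is used per-trial
        if np.any(valid.sum(axis=-1) < 2):
            raise ValueError("a trial has fewer than 2 valid samples")
        x = np.where(valid[:, None, :], trials, 0.0)
        counts = valid.sum(axis=-1)
        means = x.sum(axis=-1) / counts[:, None]
        x = np.where(valid[:, None, :], trials - means[:, :, None], 0.0)
        # within
        cw = np.zeros((n_ch, n_ch))
        for i in range(n_trials):
            cw += x[i] @ x[i].T / max(counts[i] - 1, 1)
        cw /= n_trials
        # across, pairwise-complete
        ca = np.zeros((n_ch, n_ch))
        n_pairs = 0
        for i in range(n_trials):
            for j in range(i + 1, n_trials):
                both = valid[i] & valid[j]
                nb = both.sum()
                if nb < 2:
                    continue
                xi = x[i][:, both]
                xj = x[j][:, both]
                ca += (xi @ xj.T + xj @ xi.T) / (nb - 1)
                n_pairs += 2
        if n_pairs == 0:
            raise ValueError("no trial pair has overlapping valid samples")
        ca /= n_pairs
        return 0.5 * (cw + cw.T), 0.5 * (ca + ca.T)

    x = _demean(trials)
    per_trial = np.einsum("kct,kdt->kcd", x, x)
    cw = per_trial.sum(axis=0) / (n_trials * (n_samp - 1))
    s = x.sum(axis=0)
    cross = (s @ s.T - per_trial.sum(axis=0)) / (n_trials * (n_trials - 1) * (n_samp - 1))
    cw = 0.5 * (cw + cw.T)
    ca = 0.5 * (cross + cross.T)
    return cw, ca


def _rank_for_fraction(eigvals: np.ndarray, fraction: float = 0.99) -> int:
    """Smallest rank capturing ``fraction`` of the trace."""
    ev = np.sort(eigvals)[::-1]
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    if total <= 0:
        return len(ev)
    cum = np.cumsum(ev) / total
    return int(np.searchsorted(cum, fraction) + 1)


def fit_rca(
    trials: np.ndarray,
    n_components: int = 3,
    rank: int | None = None,
    mask: np.ndarray | None = None,
    training: dict | None = None,
) -> RCModel:
    """Fit RCA weights from trials (n_trials, n_channels, n_samples).

    ``rank`` truncates C_within to its top-K principal subspace before the
    eigensolve (default: smallest K capturing 99% of the trace).  Each
    component's sign is fixed so its forward-model topography is positive at
    the channel of maximum absolute loading.
    """
    cw, ca = trial_covariances(trials, mask)
    n_ch = cw.shape[0]
    if rank is None:
        rank = _rank_for_fraction(np.linalg.eigvalsh(cw))
    if rank > n_ch:
        raise ValueError("rank cannot exceed the channel count")
    evals, evecs = np.linalg.eigh(cw)
    order = np.argsort(evals)[::-1][:rank]
    lam = evals[order]
    if lam[-1] <= 0 or lam[-1] / lam[0] < 1e-12:
        raise np.linalg.LinAlgError(
            "within-trial covariance singular on the requested subspace; "
            "lower the regularization rank"
        )
    whiten = evecs[:, order] / np.sqrt(lam)
    m = whiten.T @ ca @ whiten
    m = 0.5 * (m + m.T)
    rel, u = np.linalg.eigh(m)
    idx = np.argsort(rel)[::-1][:n_components]
    w = whiten @ u[:, idx]
    rel = rel[idx]
    a = forward_model(w, cw)
    for c in range(w.shape[1]):
        peak = np.argmax(np.abs(a[:, c]))
        if a[peak, c] < 0:
            w[:, c] *= -1
            a[:, c] *= -1
    return RCModel(weights=w, reliabilities=rel, forward=a, rank=rank, training=training)


def forward_model(weights: np.ndarray, c_pooled: np.ndarray) -> np.ndarray:
    """Forward model A = C W (W' C W)^-1 mapping components to sensor space."""
    w = np.atleast_2d(weights)
    if w.shape[0] == 1:
        w = w.T
    gram = w.T @ c_pooled @ w
    if np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError("W' C W is singular")
    return c_pooled @ w @ np.linalg.inv(gram)


def project(trials: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Project trials (..., n_channels, n_samples) into component space.

    Returns (..., n_components, n_samples).  Linear; NaNs used as missing
    markers propagate through the product.
    """
    trials = np.asarray(trials, dtype=float)
    w = np.atleast_2d(weights)
    if w.shape[0] == 1:
        w = w.T
    if trials.shape[-2] != w.shape[0]:
        raise ValueError("channel dimension mismatch")
    return np.einsum("...ct,ck->...kt", trials, w)


# ---------------------------------------------------------------------------
# TrialSet conveniences
# ---------------------------------------------------------------------------

def _pool_trials(ts: TrialSet, stimulus: str) -> np.ndarray:
    """All trials of one disparity stimulus type, pooled across subjects and
    task conditions: (n_pooled, n_channels, n_samples)."""
    idx = [i for i, c in enumerate(ts.conditions) if c.startswith(stimulus + ":")]
    if not idx:
        raise ValueError(f"no conditions of stimulus type {stimulus!r}")
    sel = ts.data[:, idx]  # (S, C_sel, K, ch, T)
    return sel.reshape(-1, sel.shape[-2], sel.shape[-1])


def fit_rca_trialset(
    ts: TrialSet,
    stimulus: str,
    n_components: int = 3,
    rank: int | None = None,
    prefilter: bool = True,
) -> RCModel:
    """Fit one model per disparity stimulus type from a TrialSet.

    Trials of both task conditions of the given stimulus type are pooled;
    by default the nF1-clean filter is applied first (weights are learned on
    dot-update-free data).
    """
    pooled = _pool_trials(ts, stimulus)
    if prefilter:
        spec = FilterSpec("nf1_clean", f1=ts.f1, f2=ts.f2)
        pooled = apply_spectral_filter(pooled, spec, ts.sampling_rate)
    return fit_rca(
        pooled, n_components=n_components, rank=rank,
        training={"stimulus": stimulus, "pooled_conditions": "tasks"},
    )


def project_trialset(ts: TrialSet, model: RCModel, component: int = 0) -> np.ndarray:
    """Project every trial onto one component: (S, C, K, n_samples)."""
    w = model.weights[:, [component]]
    out = project(ts.data, w)
    return out[..., 0, :]
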