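"""Dynamic random-dot stereogram (DRDS) stimulus model.

A circular field of non-overlapping black/white dots is regenerated at the
dot-update rate F2 (20 Hz) while the binocular disparity of the field
alternates at F1 (1.4 Hz) between a "disparity on" and a "disparity off"
(zero-disparity) state.  In the *plane* configuration the on-state carries a
uniform crossed disparity; in the *grating* configuration the disparity
varies sinusoidally with vertical position between 0 arcmin (troughs) and
the full amplitude (peaks), adding relative-disparity structure.

The module also models the behavioural side of the experiment: the adaptive
staircase that keeps nonius-line colour-change detection at 82% correct, the
random probe-time schedule, and the session bookkeeping (3 sets of 10 trials
per condition).

Sign convention for crossed disparity: the left half-image is shifted +d/2
(rightward) and the right half-image -d/2, so the total interocular offset
equals the disparity profile value d at the dot's vertical position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StimulusConfig",
    "DotField",
    "StereoFrame",
    "StaircaseState",
    "disparity_profile",
    "generate_dot_field",
    "render_stereo_frame",
    "frame_schedule",
    "first_off_transition_ms",
    "disparity_state_samples",
    "staircase_step",
    "run_staircase",
    "probe_times",
    "session_plan",
    "CONDITIONS",
]

#: The four experimental conditions: stimulus type x task.
CONDITIONS = (
    "plane:attend_fixation",
    "plane:attend_stimulus",
    "grating:attend_fixation",
    "grating:attend_stimulus",
)


@dataclass(frozen=True)
class StimulusConfig:
    """Geometric and temporal parameters of the DRDS display.

    Lengths are degrees of visual angle unless a field name says arcmin;
    rates are Hz, durations seconds.
    """

    field_radius: float = 13.65
    dot_density: float = 15.0          # dots per square degree
    dot_diameter_arcmin: float = 6.0
    disparity_amplitude_arcmin: float = 6.0  # peak crossed disparity
    grating_sf: float = 0.5            # cycles/deg of the disparity grating
    f1: float = 1.4                    # disparity on/off modulation rate
    f2: float = 20.0                   # dot regeneration rate
    frame_rate: float = 60.0
    fusion_lock_size: float = 39.5     # side of the square 1/f fusion frame
    uncorrelated_band_width: float = 1.2
    nonius_extent: float = 1.0
    active_duration: float = 10.0
    prelude_duration: float = 1.0
    postlude_duration: float = 1.0
    # Phase of the disparity grating: -pi/2 puts a trough at field centre
    # (y = 0); the original report does not state the phase.
    grating_phase: float = -math.pi / 2

    def __post_init__(self) -> None:
        positive = (
            "field_radius", "dot_diameter_arcmin", "grating_sf", "f1", "f2",
            "frame_rate", "fusion_lock_size", "uncorrelated_band_width",
            "nonius_extent", "active_duration",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dot_density < 0:
            raise ValueError("dot_density must be >= 0")
        if self.disparity_amplitude_arcmin < 0:
            raise ValueError("disparity_amplitude_arcmin must be >= 0")
        if self.prelude_duration < 0 or self.postlude_duration < 0:
            raise ValueError("prelude/postlude durations must be >= 0")
        ratio = self.frame_rate / self.f2
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "frame_rate must be an integer multiple of the dot update "
                f"rate f2 (got {self.frame_rate}/{self.f2})"
            )

    @property
    def dot_diameter(self) -> float:
        """Dot diameter in degrees."""
        return self.dot_diameter_arcmin / 60.0

    @property
    def frames_per_dot_update(self) -> int:
        return round(self.frame_rate / self.f2)


@dataclass
class DotField:
    """A set of dots: positions (n, 2) in degrees and +-1 contrast polarity."""

    positions: np.ndarray
    polarities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.polarities = np.asarray(self.polarities).reshape(-1)
        if self.positions.shape[0] != self.polarities.shape[0]:
            raise ValueError("positions and polarities must have equal length")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class StereoFrame:
    """One rendered left/right half-image pair.

    ``regions`` labels each dot of the correlated structure ("drds"),
    the binocularly uncorrelated annulus ("uncorrelated_band") or the static
    zero-disparity surround ("fusion_lock").  Fusion-lock dots are identical
    in the two eyes; band dots are drawn independently per eye.
    """

    left_dots: DotField
    right_dots: DotField
    left_regions: np.ndarray
    right_regions: np.ndarray
    disparity_state: str  # "on" | "off"


# ---------------------------------------------------------------------------
# Disparity profiles
# ---------------------------------------------------------------------------

def disparity_profile(y, kind: str, cfg: StimulusConfig | None = None):
    """Crossed disparity (arcmin) at vertical position ``y`` (degrees).

    ``plane`` is constant at the full amplitude; ``grating`` sweeps
    sinusoidally between 0 at the troughs and the amplitude at the peaks:
    d(y) = (A/2) * (1 + sin(2 pi sf y + phi0)).
    """
    cfg = cfg or StimulusConfig()
    y_arr = np.asarray(y, dtype=float)
    if np.any(np.abs(y_arr) > cfg.field_radius + 1e-12):
        raise ValueError("y outside the stimulus field")
    if kind == "plane":
        out = np.full_like(y_arr, cfg.disparity_amplitude_arcmin)
    elif kind == "grating":
        out = 0.5 * cfg.disparity_amplitude_arcmin * (
            1.0 + np.sin(2.0 * math.pi * cfg.grating_sf * y_arr + cfg.grating_phase)
        )
    else:
        raise ValueError(f"unknown disparity profile kind: {kind!r}")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Dot field generation (rejection sampling with a neighbour grid)
# ---------------------------------------------------------------------------

_MAX_RETRIES_PER_DOT = 10_000


def _sample_nonoverlapping(n: int, sampler, min_dist: float, rng) -> np.ndarray:
    """Place ``n`` points with pairwise distance >= min_dist.

    ``sampler(rng)`` draws one candidate (x, y).  Uses a uniform grid with
    cell size min_dist so each candidate only checks its 3x3 neighbourhood.
    """
    if n == 0:
        return np.empty((0, 2))
    pts = np.empty((n, 2))
    cell = min_dist if min_dist > 0 else 1.0
    grid: dict[tuple[int, int], list[int]] = {}
    min_d2 = min_dist * min_dist
    for i in range(n):
        for _ in range(_MAX_RETRIES_PER_DOT):
            p = sampler(rng)
            cx, cy = int(math.floor(p[0] / cell)), int(math.floor(p[1] / cell))
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for j in grid.get((cx + dx, cy + dy), ()):
                        d = pts[j] - p
                        if d[0] * d[0] + d[1] * d[1] < min_d2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                pts[i] = p
                grid.setdefault((cx, cy), []).append(i)
                break
        else:
            raise RuntimeError(
                "dot density infeasible: rejection sampling exceeded "
                f"{_MAX_RETRIES_PER_DOT} retries for dot {i}"
            )
    return pts


def _disk_sampler(radius: float):
    def sample(rng):
        while True:
            p = rng.uniform(-radius, radius, size=2)
            if p[0] * p[0] + p[1] * p[1] <= radius * radius:
                return p
    return sample


def _annulus_sampler(r_in: float, r_out: float):
    def sample(rng):
        while True:
            p = rng.uniform(-r_out, r_out, size=2)
            r2 = p[0] * p[0] + p[1] * p[1]
            if r_in * r_in <= r2 <= r_out * r_out:
                return p
    return sample


def _square_annulus_sampler(half_in: float, half_out: float):
    def sample(rng):
        while True:
            p = rng.uniform(-half_out, half_out, size=2)
            if max(abs(p[0]), abs(p[1])) >= half_in:
                return p
    return sample


def _polarities(n: int, rng) -> np.ndarray:
    return rng.choice([-1, 1], size=n)


def generate_dot_field(cfg: StimulusConfig, rng_seed=0) -> DotField:
    """Draw one non-overlapping dot field filling the circular DRDS region.

    The dot count is round(density * field area); placement is rejection
    sampling, deterministic given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    area = math.pi * cfg.field_radius ** 2
    n = round(cfg.dot_density * area)
    pts = _sample_nonoverlapping(n, _disk_sampler(cfg.field_radius), cfg.dot_diameter, rng)
    return DotField(pts, _polarities(n, rng))


# ---------------------------------------------------------------------------
# Stereo rendering
# ---------------------------------------------------------------------------

def render_stereo_frame(
    dots: DotField,
    kind: str,
    state: str,
    cfg: StimulusConfig | None = None,
    rng_seed=0,
) -> StereoFrame:
    """Render one stereo half-image pair from a correlated dot field.

    In the ``on`` state each correlated dot pair is offset horizontally by
    the profile value at its vertical position (+d/2 left eye, -d/2 right
    eye, crossed sign convention); in the ``off`` state the DRDS region is
    identical between eyes.  The uncorrelated band is drawn independently
    per eye; the fusion-lock surround is identical per eye.
    """
    cfg = cfg or StimulusConfig()
    if state not in ("on", "off"):
        raise ValueError("state must be 'on' or 'off'")
    rng = np.random.default_rng(rng_seed)

    if state == "on":
        d_arcmin = disparity_profile(dots.positions[:, 1], kind, cfg)
        shift = np.asarray(d_arcmin, dtype=float) / 60.0 / 2.0  # deg, half each eye
    else:
        shift = np.zeros(len(dots))
    left_drds = dots.positions.copy()
    right_drds = dots.positions.copy()
    left_drds[:, 0] += shift
    right_drds[:, 0] -= shift

    # Binocularly uncorrelated annulus between field edge and fusion lock.
    r_in = cfg.field_radius
    r_out = cfg.field_radius + cfg.uncorrelated_band_width
    band_area = math.pi * (r_out ** 2 - r_in ** 2)
    n_band = round(cfg.dot_density * band_area)
    band_sampler = _annulus_sampler(r_in, r_out)
    band_left = _sample_nonoverlapping(n_band, band_sampler, cfg.dot_diameter, rng)
    band_right = _sample_nonoverlapping(n_band, band_sampler, cfg.dot_diameter, rng)
    band_pol_left = _polarities(n_band, rng)
    band_pol_right = _polarities(n_band, rng)

    # Static zero-disparity fusion-lock texture, identical in both eyes.
    half_out = cfg.fusion_lock_size / 2.0
    half_in = min(r_out, half_out)
    lock_area = max(cfg.fusion_lock_size ** 2 - (2 * half_in) ** 2, 0.0)
    # sparse texture: the real display uses a 1/f image, dots stand in here
    n_lock = round(0.25 * cfg.dot_density * lock_area)
    lock = _sample_nonoverlapping(
        n_lock, _square_annulus_sampler(half_in, half_out), cfg.dot_diameter, rng
    )
    lock_pol = _polarities(n_lock, rng)

    def eye(drds_pos, band_pos, band_pol):
        pos = np.vstack([drds_pos, band_pos, lock])
        pol = np.concatenate([dots.polarities, band_pol, lock_pol])
        regions = np.concatenate([
            np.repeat("drds", len(dots)),
            np.repeat("uncorrelated_band", n_band),
            np.repeat("fusion_lock", n_lock),
        ])
        return DotField(pos, pol), regions

    left, left_regions = eye(left_drds, band_left, band_pol_left)
    right, right_regions = eye(right_drds, band_right, band_pol_right)
    return StereoFrame(left, right, left_regions, right_regions, state)


# ---------------------------------------------------------------------------
# Temporal schedule
# ---------------------------------------------------------------------------

def first_off_transition_ms(cfg: StimulusConfig | None = None) -> float:
    """Time of the first on->off disparity transition, in ms.

    The cycle starts in the on state, so the off transition falls at half
    the F1 period (357.14 ms at 1.4 Hz; exactly 150 samples at 420 Hz).
    """
    cfg = cfg or StimulusConfig()
    return 1000.0 / (2.0 * cfg.f1)


def disparity_state_samples(f1: float, fs: float, n_samples: int) -> np.ndarray:
    """Boolean on/off square wave in the analysis sample domain.

    Requires fs/f1 to be an integer number of samples per cycle (300 at
    420 Hz / 1.4 Hz), in which case the sequence has that exact period with
    a 50% duty cycle, starting in the on state.
    """
    period = fs / f1
    if abs(period - round(period)) > 1e-9:
        raise ValueError("fs must be an integer multiple of f1")
    period = round(period)
    half = period // 2
    if 2 * half != period:
        raise ValueError("samples per cycle must be even for a 50% duty cycle")
    one_cycle = np.concatenate([np.ones(half, bool), np.zeros(half, bool)])
    reps = int(np.ceil(n_samples / period))
    return np.tile(one_cycle, reps)[:n_samples]


def frame_schedule(cfg: StimulusConfig | None = None) -> pd.DataFrame:
    """Per-video-frame table of disparity state and dot regeneration.

    Columns: frame, time_s, phase (prelude|active|postlude),
    disparity_state ("on"/"off"), regenerate_dots.  Disparity transitions at
    multiples of 1/(2 f1) are rounded to the nearest video frame; dots are
    regenerated on every ``frames_per_dot_update``-th active frame.  The
    prelude/postlude recycle the first/last 60 active frames.
    """
    cfg = cfg or StimulusConfig()
    n_active = round(cfg.active_duration * cfg.frame_rate)
    frames = np.arange(n_active)
    t = frames / cfg.frame_rate
    # number of half-periods completed by each (nearest-frame-rounded) time
    half_period = 1.0 / (2.0 * cfg.f1)
    k_max = int(math.ceil(cfg.active_duration / half_period)) + 1
    transition_frames = np.round(np.arange(1, k_max + 1) * half_period * cfg.frame_rate)
    n_transitions = np.searchsorted(transition_frames, frames, side="right")
    state = np.where(n_transitions % 2 == 0, "on", "off")
    regen = frames % cfg.frames_per_dot_update == 0
    active = pd.DataFrame({
        "frame": frames,
        "time_s": t,
        "phase": "active",
        "disparity_state": state,
        "regenerate_dots": regen,
    })

    n_pre = round(cfg.prelude_duration * cfg.frame_rate)
    n_post = round(cfg.postlude_duration * cfg.frame_rate)
    prelude = active.iloc[:n_pre].copy()
    prelude["phase"] = "prelude"
    postlude = active.iloc[n_active - n_post:].copy()
    postlude["phase"] = "postlude"
    out = pd.concat([prelude, active, postlude], ignore_index=True)
    out["frame"] = np.arange(len(out))
    out["time_s"] = out["frame"] / cfg.frame_rate
    return out


# ---------------------------------------------------------------------------
# Behavioural task: staircase, probes, session plan
# ---------------------------------------------------------------------------

@dataclass
class StaircaseState:
    """Weighted up-down (Kaernbach) staircase on probe duration.

    Steps are multiplicative (additive in log-duration).  At equilibrium the
    probability of a correct response satisfies
    p * step_down = (1 - p) * step_up, so the default step ratio
    step_up/step_down = 0.82/0.18 converges to 82% correct regardless of the
    observer's psychometric slope.
    """

    current_duration: float = 0.3
    target_accuracy: float = 0.82
    step_down: float = 0.05  # log-units, applied after a correct response
    step_up: float = 0.05 * 0.82 / 0.18
    bounds: tuple[float, float] = (0.01, 0.5)
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (0 < lo < hi):
            raise ValueError("invalid duration bounds")
        if not (0 < self.target_accuracy < 1):
            raise ValueError("target_accuracy must be in (0, 1)")
        if self.step_down <= 0 or self.step_up <= 0:
            raise ValueError("step sizes must be positive")
        self.current_duration = float(np.clip(self.current_duration, lo, hi))


def staircase_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase one trial: correct -> shorter (harder) probe."""
    log_d = math.log(state.current_duration)
    log_d += -state.step_down if correct else state.step_up
    lo, hi = state.bounds
    new_d = float(np.clip(math.exp(log_d), lo, hi))
    return replace(
        state,
        current_duration=new_d,
        history=state.history + [(state.current_duration, bool(correct))],
    )


def run_staircase(observer, n_trials: int, state: StaircaseState | None = None) -> StaircaseState:
    """Run ``n_trials`` of the staircase against ``observer(duration) -> bool``."""
    state = state or StaircaseState()
    for _ in range(n_trials):
        state = staircase_step(state, observer(state.current_duration))
    return state


def probe_times(trial_duration: float = 10.0, rng_seed=0) -> np.ndarray:
    """Random colour-change probe onsets within one active trial.

    First probe uniform in [2, 3] s after trial start, subsequent probes
    spaced uniformly in [2.5, 5] s, truncated at the trial end.
    """
    rng = np.random.default_rng(rng_seed)
    times = [rng.uniform(2.0, 3.0)]
    while True:
        nxt = times[-1] + rng.uniform(2.5, 5.0)
        if nxt >= trial_duration:
            break
        times.append(nxt)
    return np.asarray(times)


def session_plan(
    conditions=CONDITIONS,
    n_sets_per_condition: int = 3,
    trials_per_set: int = 10,
    rng_seed=0,
) -> pd.DataFrame:
    """Randomized session schedule: sets of same-condition trials.

    Each condition appears in ``n_sets_per_condition`` sets of
    ``trials_per_set`` trials (3 x 10 = 30 trials per condition by default);
    set order is shuffled.
    """
    rng = np.random.default_rng(rng_seed)
    sets = [c for c in conditions for _ in range(n_sets_per_condition)]
    rng.shuffle(sets)
    rows = [
        {"set_index": s, "condition": cond, "trial_in_set": k}
        for s, cond in enumerate(sets)
        for k in range(trials_per_set)
    ]
    return pd.DataFrame(rows)
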