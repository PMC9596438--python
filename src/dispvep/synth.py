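"""Synthetic trial-structured EEG with planted disparity-response structure.

The generator emulates a steady-state disparity VEP experiment: a transient
source (identical biphasic deflections at the disparity on and off
transitions, hence energy only at even multiples of F1), a sustained source
(half-cycle-antisymmetric, hence odd multiples of F1 only), and a 20 Hz
dot-update response, each mixed through a smooth occipital scalp topography,
plus spatially correlated 1/f noise and white sensor noise.

Condition structure mirrors the experiment's 2 x 2 design:

* the sustained source's amplitude in the *plane* conditions is 1/8 of its
  amplitude in the *grating* conditions (absolute-disparity-only stimuli
  drive little odd-harmonic activity);
* in *attend-stimulus* conditions an additive "task-extra" sustained
  component switches on at ``task_effect_onset`` ms after the disparity-on
  transition, so the planted onset of the attention effect is sharply
  defined.

Between-subject amplitude variability is log-normal.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stimulus import CONDITIONS

__all__ = [
    "SourceSpec",
    "SimConfig",
    "TrialSet",
    "channel_layout",
    "make_topographies",
    "source_cycle_waveform",
    "source_epoch_waveform",
    "default_sources",
    "simulate_dataset",
    "pink_noise",
    "simulate_eog",
    "observer_probability",
    "simulate_observer",
    "make_observer",
]

_PLANE_ODD_SCALE = 1.0 / 8.0  # plane odd-harmonic amplitude relative to grating


@dataclass(frozen=True)
class SourceSpec:
    """One planted neural source.

    ``kind`` selects the waveform family: ``transient`` (even harmonics),
    ``sustained`` (odd harmonics) or ``dot_update`` (sinusoid at F2).
    Latencies are ms relative to the disparity-on transition.  ``task_gain``
    multiplies the sustained response from ``task_effect_onset`` onward in
    attend-stimulus conditions (implemented as an additive component so the
    onset is sharp).
    """

    kind: str
    amplitude: float = 1.0            # µV
    onset_latency: float | None = None  # ms; defaults: transient 75, sustained 100
    peak_latency: float = 100.0       # ms, transient positive peak
    task_gain: float = 1.0
    task_effect_onset: float = 184.0  # ms
    topography_center: tuple[float, float] = (0.0, -0.75)
    rise_time: float = 10.0           # ms, sustained boxcar edge smoothing

    def __post_init__(self) -> None:
        if self.kind not in ("transient", "sustained", "dot_update"):
            raise ValueError(f"unknown source kind: {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.task_gain <= 0:
            raise ValueError("task_gain must be > 0")

    @property
    def onset(self) -> float:
        if self.onset_latency is not None:
            return self.onset_latency
        return {"transient": 75.0, "sustained": 100.0, "dot_update": 0.0}[self.kind]


@dataclass(frozen=True)
class SimConfig:
    """Simulation layout and noise parameters.

    Defaults are the study conditions: 20 subjects, 30 trials for each of
    the four conditions, 128 channels at 420 Hz, 10 s active trials
    (14 disparity cycles of 300 samples).  ``noise_amplitude`` is the
    single-channel RMS (µV) of the spatially correlated 1/f background;
    ``sensor_noise_amplitude`` the RMS of channel-independent white noise.
    """

    n_subjects: int = 20
    n_trials_per_condition: int = 30
    conditions: tuple = CONDITIONS
    n_channels: int = 128
    sampling_rate: float = 420.0
    active_duration: float = 10.0
    f1: float = 1.4
    f2: float = 20.0
    noise_exponent: float = 1.0
    noise_amplitude: float = 10.0
    sensor_noise_amplitude: float = 2.0
    n_noise_sources: int = 20
    subject_gain_sd: float = 0.3  # sd of log-normal amplitude gains
    seed: int = 0
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        period = self.sampling_rate / self.f1
        if abs(period - round(period)) > 1e-9:
            raise ValueError("sampling_rate must be an integer multiple of f1")
        n_samp = self.active_duration * self.sampling_rate
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("active_duration must be an integer number of samples")
        if round(n_samp) % round(period):
            raise ValueError("trial must contain an integer number of F1 cycles")

    @property
    def cycle_samples(self) -> int:
        return round(self.sampling_rate / self.f1)

    @property
    def n_samples(self) -> int:
        return round(self.active_duration * self.sampling_rate)

    @property
    def n_cycles(self) -> int:
        return self.n_samples // self.cycle_samples


@dataclass
class TrialSet:
    """Trial-structured EEG: subjects x conditions x trials x channels x time (µV)."""

    data: np.ndarray
    sampling_rate: float
    f1: float
    f2: float
    conditions: tuple
    channel_positions: np.ndarray  # (n_channels, 2) layout coordinates
    mask: np.ndarray | None = None  # True = sample excluded, broadcastable to data

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError("data must be 5-D (subjects, conditions, trials, channels, time)")
        if self.data.shape[1] != len(self.conditions):
            raise ValueError("condition axis does not match condition labels")
        if self.mask is not None and self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match data shape")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def cycle_samples(self) -> int:
        return round(self.sampling_rate / self.f1)

    def condition_index(self, name: str) -> int:
        return self.conditions.index(name)


# ---------------------------------------------------------------------------
# Layout and topographies
# ---------------------------------------------------------------------------

def channel_layout(n_channels: int = 128) -> np.ndarray:
    """Procedural quasi-geodesic 2-D sensor layout on the unit disk.

    A sunflower (Fibonacci) spiral gives near-uniform coverage comparable to
    a geodesic net flattened by azimuthal projection.  Negative y is
    posterior.  No proprietary montage file is involved.
    """
    k = np.arange(n_channels) + 0.5
    r = np.sqrt(k / n_channels)
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def make_topographies(n_channels: int, layout: np.ndarray, centers, width: float = 0.35) -> np.ndarray:
    """Unit-norm Gaussian-blob mixing columns centred at ``centers``.

    Returns (n_channels, n_sources).  Raises if there are more sources than
    channels (the mixing would be rank deficient in the noiseless model).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if layout.shape[0] != n_channels:
        raise ValueError("layout must provide one position per channel")
    if n_channels < centers.shape[0]:
        raise ValueError("more sources than channels")
    d2 = ((layout[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    cols = np.exp(-d2 / (2.0 * width ** 2))
    return cols / np.linalg.norm(cols, axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# Source waveforms
# ---------------------------------------------------------------------------

def _smoothstep(t: np.ndarray, t0: float, rise: float) -> np.ndarray:
    """Raised-cosine step from 0 (t <= t0) to 1 (t >= t0 + rise)."""
    x = np.clip((t - t0) / max(rise, 1e-9), 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(math.pi * x)


def _transient_half_cycle(t_ms: np.ndarray, spec: SourceSpec) -> np.ndarray:
    """Biphasic deflection, exactly zero before the onset latency."""
    pos = np.exp(-0.5 * ((t_ms - spec.peak_latency) / 12.0) ** 2)
    neg = -0.8 * np.exp(-0.5 * ((t_ms - (spec.peak_latency + 60.0)) / 20.0) ** 2)
    w = (pos + neg) * _smoothstep(t_ms, spec.onset, 8.0)
    w[t_ms < spec.onset] = 0.0
    return w


def source_cycle_waveform(spec: SourceSpec, cfg: SimConfig) -> np.ndarray:
    """One F1-cycle waveform (``cfg.cycle_samples`` samples), peak-normalized
    to ``spec.amplitude`` µV.

    * transient: the same biphasic deflection inserted at the on (0 ms) and
      off (T/2) transitions — satisfies w(t + T/2) = w(t) exactly, so its
      energy (beyond DC) lies only at even multiples of F1;
    * sustained: a smoothed 50%-duty boxcar delayed by the onset latency and
      made exactly half-cycle antisymmetric, w(t + T/2) = -w(t) — odd
      multiples of F1 only.  Negative-going during the disparity-on phase.
    * dot_update: sinusoid at F2 (phase 0 at cycle start).
    """
    n = cfg.cycle_samples
    t_ms = np.arange(n) * 1000.0 / cfg.sampling_rate
    cycle_ms = n * 1000.0 / cfg.sampling_rate
    if not (0.0 <= spec.onset < cycle_ms):
        raise ValueError("onset latency must fall inside one cycle")
    half = n // 2

    if spec.kind == "transient":
        g = _transient_half_cycle(t_ms, spec)
        g[t_ms >= cycle_ms / 2.0] = 0.0  # confine to one half before duplication
        w = g + np.roll(g, half)
    elif spec.kind == "sustained":
        u = _smoothstep(t_ms, spec.onset, spec.rise_time)
        u = u * (1.0 - _smoothstep(t_ms, spec.onset + cycle_ms / 2.0, spec.rise_time))
        w = -(u - np.roll(u, -half)) / 2.0  # exact odd symmetry, negative on-phase
    elif spec.kind == "dot_update":
        w = np.sin(2.0 * math.pi * cfg.f2 * t_ms / 1000.0)
    else:  # pragma: no cover - guarded by SourceSpec
        raise ValueError(spec.kind)
    peak = np.abs(w).max()
    if peak > 0:
        w = w * (spec.amplitude / peak)
    return w


def source_epoch_waveform(spec: SourceSpec, cfg: SimConfig) -> np.ndarray:
    """Full-epoch trace.  Cyclic sources tile their cycle waveform; the dot
    update is generated continuously (F2 is not an integer multiple of F1,
    so a tiled single cycle would be discontinuous)."""
    if spec.kind == "dot_update":
        t = np.arange(cfg.n_samples) / cfg.sampling_rate
        return spec.amplitude * np.sin(2.0 * math.pi * cfg.f2 * t)
    return np.tile(source_cycle_waveform(spec, cfg), cfg.n_cycles)


def _task_extra_waveform(spec: SourceSpec, cfg: SimConfig) -> np.ndarray:
    """Additive attention component switching on at ``task_effect_onset``.

    The extra activity occupies [onset, T/2) — from the planted task-effect
    onset until the disparity-off transition — and is completed to exact
    half-cycle antisymmetry, which leaves it identically zero on
    [0, onset): the planted onset is sharp, with no wrap-around leakage.
    Scaled to (task_gain - 1) times the parent source's amplitude.
    """
    n = cfg.cycle_samples
    half = n // 2
    t_ms = np.arange(n) * 1000.0 / cfg.sampling_rate
    cycle_ms = n * 1000.0 / cfg.sampling_rate
    onset = spec.task_effect_onset
    if not (0.0 <= onset < cycle_ms / 2.0):
        raise ValueError("task_effect_onset must fall inside the on half-cycle")
    u = _smoothstep(t_ms, onset, spec.rise_time)
    # the closing ramp ends exactly at T/2 so no activity wraps before onset
    u = u * (1.0 - _smoothstep(t_ms, cycle_ms / 2.0 - spec.rise_time, spec.rise_time))
    w = -(u - np.roll(u, -half)) / 2.0
    peak = np.abs(w).max()
    if peak > 0:
        w = w * (spec.amplitude * abs(spec.task_gain - 1.0) / peak)
        if spec.task_gain < 1.0:
            w = -w
    return np.tile(w, cfg.n_cycles)


def default_sources() -> list[SourceSpec]:
    """Planted sources at amplitudes giving cycle-average waveforms of a few
    µV, in line with group-level disparity VEPs."""
    return [
        SourceSpec(kind="transient", amplitude=2.0, topography_center=(0.0, -0.75)),
        SourceSpec(kind="sustained", amplitude=2.0, task_gain=1.5,
                   topography_center=(0.1, -0.65)),
        SourceSpec(kind="dot_update", amplitude=1.0, topography_center=(-0.1, -0.7)),
    ]


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def pink_noise(n_samples: int, rng, exponent: float = 1.0, size=()) -> np.ndarray:
    """1/f^gamma noise, unit RMS, shape ``size + (n_samples,)``."""
    shape = tuple(size) + (n_samples,)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    envelope = np.ones_like(freqs)
    envelope[1:] = freqs[1:] ** (-exponent / 2.0)
    envelope[0] = 0.0
    x = np.fft.irfft(spec * envelope, n=n_samples, axis=-1)
    rms = np.sqrt((x ** 2).mean(axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def _condition_scale(condition: str, spec: SourceSpec) -> float:
    stimulus, _task = condition.split(":")
    if spec.kind == "sustained" and stimulus == "plane":
        return _PLANE_ODD_SCALE
    return 1.0


def simulate_dataset(cfg: SimConfig, sources: list[SourceSpec] | None = None) -> TrialSet:
    """Generate a full TrialSet under the mixing model

    data = topographies @ (subject gain * condition-scaled source epochs)
           + correlated 1/f noise + white sensor noise.
    """
    sources = default_sources() if sources is None else sources
    if not sources:
        raise ValueError("at least one source is required")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    layout = channel_layout(cfg.n_channels)
    topo = make_topographies(
        cfg.n_channels, layout, [s.topography_center for s in sources]
    )

    epochs = np.stack([source_epoch_waveform(s, cfg) for s in sources])
    task_extras = {
        i: _task_extra_waveform(s, cfg)
        for i, s in enumerate(sources)
        if s.kind == "sustained" and s.task_gain != 1.0
    }

    if cfg.subject_gain_sd > 0:
        gains = np.exp(
            cfg.subject_gain_sd * rng.standard_normal((cfg.n_subjects, len(sources)))
        )
    else:
        gains = np.ones((cfg.n_subjects, len(sources)))

    noise_topo = None
    n_noise = min(cfg.n_noise_sources, cfg.n_channels)
    if cfg.noise_amplitude > 0 and n_noise > 0:
        centers = rng.uniform(-0.9, 0.9, size=(n_noise, 2))
        noise_topo = make_topographies(cfg.n_channels, layout, centers, width=0.5)

    dtype = np.dtype(cfg.dtype)
    shape = (cfg.n_subjects, len(cfg.conditions), cfg.n_trials_per_condition,
             cfg.n_channels, cfg.n_samples)
    data = np.zeros(shape, dtype=dtype)

    for s in range(cfg.n_subjects):
        for c, condition in enumerate(cfg.conditions):
            _stim, task = condition.split(":")
            src = np.zeros((len(sources), cfg.n_samples))
            for i, spec in enumerate(sources):
                w = epochs[i] * _condition_scale(condition, spec)
                if task == "attend_stimulus" and i in task_extras:
                    w = w + task_extras[i] * _condition_scale(condition, spec)
                src[i] = gains[s, i] * w
            clean = topo @ src
            for k in range(cfg.n_trials_per_condition):
                trial = clean
                if noise_topo is not None:
                    src_noise = pink_noise(
                        cfg.n_samples, rng, cfg.noise_exponent,
                        size=(n_noise,),
                    )
                    corr = noise_topo @ src_noise
                    corr_rms = np.sqrt((corr ** 2).mean())
                    trial = trial + corr * (cfg.noise_amplitude / corr_rms)
                if cfg.sensor_noise_amplitude > 0:
                    trial = trial + cfg.sensor_noise_amplitude * rng.standard_normal(
                        (cfg.n_channels, cfg.n_samples)
                    )
                data[s, c, k] = trial
    return TrialSet(
        data=data,
        sampling_rate=cfg.sampling_rate,
        f1=cfg.f1,
        f2=cfg.f2,
        conditions=tuple(cfg.conditions),
        channel_positions=layout,
    )


# ---------------------------------------------------------------------------
# EOG simulation
# ---------------------------------------------------------------------------

def simulate_eog(
    cfg: SimConfig,
    saccade_rate: float = 1.0,
    amplitude: float = 20.0,
    condition_variance_ratio: float = 1.1,
    noise_amplitude: float = 2.0,
    seed: int | None = None,
):
    """Simulated bipolar HEOG/VEOG traces for two attention conditions.

    Saccade-like steps occur at Poisson times (``saccade_rate`` per second)
    with Gaussian amplitudes (µV); white noise is added on top.  The second
    condition's trace is scaled so its variance is
    ``condition_variance_ratio`` times the first's.  The random stream is
    independent of the VEP generator (separate seed branch).

    Returns dict with keys ``heog`` and ``veog``, each an array of shape
    (n_subjects, 2, n_trials, n_samples); condition axis order is
    (attend_fixation, attend_stimulus).
    """
    if saccade_rate < 0 or amplitude < 0 or noise_amplitude < 0:
        raise ValueError("rates and amplitudes must be >= 0")
    base_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 0x0E06]))
    n = cfg.n_samples
    shape = (cfg.n_subjects, 2, cfg.n_trials_per_condition, n)
    out = {}
    sqrt_ratio = math.sqrt(condition_variance_ratio)
    for key in ("heog", "veog"):
        p_step = saccade_rate / cfg.sampling_rate
        steps = rng.random(shape) < p_step
        jumps = np.where(steps, rng.standard_normal(shape) * amplitude, 0.0)
        traces = np.cumsum(jumps, axis=-1)
        traces -= traces.mean(axis=-1, keepdims=True) * (saccade_rate > 0)
        if noise_amplitude > 0:
            traces = traces + noise_amplitude * rng.standard_normal(shape)
        traces[:, 1] *= sqrt_ratio
        out[key] = traces
    return out


# ---------------------------------------------------------------------------
# Simulated psychophysical observer
# ---------------------------------------------------------------------------

def observer_probability(
    duration: float,
    threshold: float = 0.1,
    slope: float = 3.0,
    lapse: float = 0.0,
    target: float = 0.82,
) -> float:
    """Detection probability: logistic in log-duration, anchored so that
    p(threshold) = target when lapse = 0."""
    x = slope * math.log(duration / threshold) + math.log(target / (1.0 - target))
    p = 1.0 / (1.0 + math.exp(-x))
    return (1.0 - lapse) * p


def simulate_observer(
    duration: float,
    threshold: float = 0.1,
    slope: float = 3.0,
    lapse: float = 0.0,
    rng=None,
) -> bool:
    """One Bernoulli detection outcome for a probe of the given duration (s)."""
    if not (0.0 < duration <= 1.0):
        raise ValueError("duration out of range")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = observer_probability(duration, threshold, slope, lapse)
    return bool(rng.random() < p)


def make_observer(threshold: float = 0.1, slope: float = 3.0, lapse: float = 0.0, seed=0):
    """Stateful observer callable for driving the staircase."""
    rng = np.random.default_rng(seed)
    def observer(duration: float) -> bool:
        return simulate_observer(duration, threshold, slope, lapse, rng)
    return observer
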