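# Methods

This note documents the models implemented in `dispvep`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that matter for reproducing results.

## Stimulus model (`dispvep.stimulus`)

The dynamic random-dot stereogram is a circular field (radius 13.65°) of
non-overlapping black/white dots, 15 dots/deg², 6 arcmin diameter,
regenerated every 3rd video frame (20 Hz at a 60 Hz display). Disparity
alternates at F1 = 1.4 Hz between "on" and "off" (zero) states with 50%
duty cycle, starting on. Two profiles:

- plane: d(y) = A (uniform crossed disparity, A = 6 arcmin);
- grating: d(y) = (A/2)(1 + sin(2π·0.5·y + φ₀)), ranging 0 at troughs to A
  at peaks. φ₀ defaults to −π/2, putting a trough at the field centre;
  the choice is free (the display geometry does not pin it down) and
  configurable.

Sign convention: crossed disparity shifts the left half-image +d/2 and the
right −d/2, so the interocular offset equals d. A 1.2°-wide annulus of
binocularly uncorrelated dots separates the field from a static
zero-disparity fusion frame (39.5° square); the frame's 1/f texture is
represented by a sparse dot texture, which is sufficient because nothing
downstream consumes its pixel statistics.

Timing is quantized twice. On the display, ideal transition times k/(2F1)
are rounded to the nearest 60 Hz frame (F1 does not divide the frame
rate). In the analysis domain the cycle is exact: at 420 Hz one F1 cycle
is 300 samples, the off transition at sample 150 = 357.14 ms. The analysis
domain is treated as authoritative for all statistics.

Non-overlap placement is rejection sampling on a neighbour grid, capped at
10⁴ retries per dot; at the default density the packing fraction is ~12%,
far from jamming, so the cap is never approached.

The behavioural staircase is a weighted up-down (Kaernbach) rule on log
probe duration, clamped to [0.01, 0.5] s: after a correct response the
duration shrinks by 0.05 log-units, after an error it grows by
0.05 × 0.82/0.18. At equilibrium p·Δdown = (1 − p)·Δup, so the procedure
converges to 82% correct *independently of the observer's psychometric
slope* — which is why staircase convergence is a meaningful end-to-end
check. The simulated observer is Bernoulli with p logistic in
log-duration, anchored so p(threshold) = 0.82 at zero lapse.

## Synthetic EEG (`dispvep.synth`)

The generator produces `TrialSet` arrays
(subjects × conditions × trials × channels × time, µV) under a linear
mixing model plus noise:

- **transient source** (even harmonics): one biphasic deflection —
  positive peak at 100 ms, trailing negativity — inserted identically at
  the on (0 ms) and off (T/2) transitions and exactly zero before its
  75 ms onset. By construction w(t + T/2) = w(t), so all non-DC energy
  sits at even multiples of F1.
- **sustained source** (odd harmonics): a raised-cosine-smoothed 50%-duty
  boxcar delayed by 100 ms, completed to exact half-cycle antisymmetry
  w(t + T/2) = −w(t); negative-going during the on phase. Energy sits at
  odd multiples of F1 only.
- **dot-update source**: a 20 Hz sinusoid generated over the whole epoch
  (F2/F1 = 100/7 is non-integer, so tiling a single F1 cycle would break
  continuity).

Condition structure: the sustained amplitude in plane conditions is 1/8 of
the grating's, and in attend-stimulus conditions an additive "task-extra"
sustained component switches on at `task_effect_onset` (default 184 ms).
The task extra occupies [onset, T/2) before antisymmetric completion; this
detail matters — completing a full-half-cycle boxcar instead would wrap
activity into [0, onset) and destroy the planted onset. An additive
component (rather than a multiplicative gate) keeps the onset sharp and
the harmonic purity exact.

Topographies are unit-norm Gaussian blobs over a procedurally generated
sunflower-spiral 128-channel layout (posterior = negative y); signal
sources sit at midline-posterior positions. Noise is spatially correlated
1/f^γ (γ = 1) built by spectrally shaping white noise and mixing through
20 random smooth topographies, at 10 µV single-channel RMS, plus 2 µV white
sensor noise. Between-subject variability is log-normal amplitude gain
(σ = 0.3). Signal amplitudes default to 2 µV (transient, sustained) and
1 µV (dot update); with 15–30 trials × 14 cycles of averaging these
produce group cycle averages of a few µV with SEMs of a few tenths of µV,
the scale typical of group-level disparity VEPs. Single-trial SNR is not
itself constrained by published values; the defaults are one fixed,
realistic choice.

What the generator does **not** emulate: biophysical head-volume
conduction, vergence dynamics, blink/saccade EEG artifacts coupled to the
VEP channels, the display trigger artifact, or reaction-time structure.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under its own assumptions (linear mixing, stationary 1/f noise,
exchangeable subjects), not robustness to every pathology of real EEG.

Full study scale (20 subjects × 4 conditions × 30 trials × 128 channels ×
10 s at 420 Hz) is ~10 GB of float64 and is supported but deliberately not
the packaged default problem size: tests and the pipeline default config
use 12–20 subjects, 10–30 trials and 16–32 channels at the *same
amplitude and noise defaults*, which leaves every per-subject and
group-level SNR property intact while keeping runs desk-scale.

EOG traces are simulated independently of the VEP stream (separate seed
branch): saccade-like Poisson step processes plus white noise, with one
attention condition's variance scaled by a configurable ratio (default
1.1, i.e. a 10% variance difference).

## Preprocessing (`dispvep.preprocess`)

Zero-phase (forward-backward) 4th-order Butterworth bandpass 0.3–50 Hz —
zero phase because any filter latency would bias the onset statistics —
followed by polyphase resampling at the rational ratio 420/500 = 21/25
(7 samples per 60 Hz frame). Artifact thresholds are per-channel
5 × 1.4826·MAD clamped into [30, 80] µV. A channel is "consistently noisy"
when >15% of its samples exceed threshold; it is replaced by the unweighted
mean of its 6 nearest good channels by layout distance. 1-s epochs with
strictly >10% of samples over threshold are masked per sensor; masked
samples propagate into covariance estimation as pairwise-complete
exclusions, never silent zeros. More than 25% bad channels aborts.

## Harmonic filters (`dispvep.harmonics`)

Filters operate on whole 10 s epochs (0.1 Hz bin resolution) *before*
cycle averaging; per-cycle filtering would alias the 1F1 bin. Kept-bin
matching uses exact rational arithmetic (`fractions.Fraction`) on
f × N / fs, never floating-point equality; epochs must contain an integer
number of F1 cycles and no taper is applied (the steady-state design makes
the harmonics exactly bin-aligned). DC is always removed, so reconstructed
cycle averages are mean-free. With F1 = 1.4 and F2 = 20 Hz the harmonic
sets first collide at 140 Hz, so below the 50 Hz low-pass `nf1_clean`
keeps all 35 F1 harmonics.

## RCA (`dispvep.rca`)

C_within is the trial-average channel covariance; C_across the symmetrized
average of cross-covariances over ordered trial pairs at identical
timepoints (equal to C_within for identical trials). The generalized
eigenproblem is solved by whitening on the rank-K principal subspace of
C_within; K defaults to the smallest rank capturing 99% of the trace.
Weights are learned on nF1-clean filtered trials pooled across task
conditions but *within* each disparity stimulus type (separate plane and
grating models), then all conditions are projected through the matching
RC1. Component signs are fixed so the forward-model topography is positive
at its largest-|loading| channel; the sign is otherwise arbitrary.
The across-trial average pools all trial pairs within the pooled trial set
(subjects' trials concatenated); pooling order is configurable in
principle but immaterial for the balanced designs generated here.

## Statistics (`dispvep.stats`)

Permutations flip the A/B condition labels independently per subject —
sign flips of the paired difference waveforms, the natural exchangeability
unit of a paired design. Per permutation the longest run of pointwise
p < .05 is recorded; the threshold is the conservative ("higher"-method)
95th percentile of that null, and observed runs must *strictly* exceed it.
Defaults: 2000 permutations, seeded; 500 are used in the heavier test
loops.

A structural property worth knowing: when an effect is large *and* nearly
homogeneous across subjects, an unbalanced sign-flip with imbalance
f = (2k − n)/n yields |t| = f√(n−1)/√(1−f²) throughout the effect window,
independent of effect size. For some n this crosses the pointwise
criterion in slightly more than 5% of permutations, pushing the null 95th
percentile up to the full window length and making the corrected test
conservative. This is intrinsic to run-length max-statistic permutation
testing with a strict threshold, not an implementation artifact; it is
invisible at realistic SNR, where between-subject variability dominates.

Jackknife onsets: each leave-one-subject-out iteration reruns the
corrected test and records the first timepoint of the first surviving
segment. The estimate reports the median, a jackknife-SE interval
(median ± 1.96·SE with the (n−1)/n variance inflation) and a percentile
interval; iterations with no surviving segment are tolerated up to half,
beyond which the effect is declared too weak to time. `compare_onsets`
applies a naive paired t to the leave-one-out values by default (df =
n − 1); because jackknife replicates are strongly shrunken toward the
mean, this overstates evidence, so a Miller–Ulrich-style correction
(t/(n − 1)) is available behind `corrected=True`.

Bayes factors are JZS with Cauchy prior scale √2/2, computed by adaptive
quadrature of Rouder's g-integral in log space (relative tolerance 1e-8,
offset by the integrand maximum to avoid overflow at large t). The
implementation agrees with pingouin's to ~1e-4 relative and reproduces
BF₁₀ = 2.25 × 10⁹ at t(19) = 15.44. Windowed summaries are the arithmetic
mean of per-timepoint BF₁₀ over a time window.

## EOG control (`dispvep.eog`)

Bipolar HEOG/VEOG are channel differences of named periocular pairs.
Variability is the sample SD over time of each subject's *condition-mean*
trace (not single trials). The modulation index |σ²_A − σ²_B|/(σ²_A + σ²_B)
is symmetric, scale-invariant and bounded in [0, 1]; eye-movement and VEP
attention indices are compared by Pearson correlation across subjects.

## Pipeline (`dispvep.pipeline`)

One global seed is expanded into per-stage SeedSequence substreams keyed
by fixed stage indices, so adding a stage never perturbs earlier stages'
draws; identical config + seed gives byte-identical result JSON (verified
by manifest hash). Units are µV and ms throughout; the results schema is
versioned. EDF, BrainVision and FIF recordings are read via mne; the
written interchange formats are HDF5 (TrialSet) and FIF (single trials).

## Known limitations

- The run-length correction's conservativeness under homogeneous strong
  effects (above).
- Bad-channel interpolation uses unweighted neighbour means; no spherical
  spline.
- `compare_onsets`' default naive t inherits the anti-conservativeness of
  testing jackknife replicates directly; use `corrected=True` for
  conservative inference.
- The generator's noise is stationary; drifts, blinks and line noise are
  out of scope, as are source localization and ICA-based artifact removal.
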