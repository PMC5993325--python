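# Methods

This note records the model, the generators, the numerical choices, and the
places where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Run-length inference model

**Generative assumptions.** Pitches are modelled as draws from a D-variate
Gaussian over sliding D-tuples of successive tones, with unknown mean and
covariance that change at unknown changepoints; runs between changepoints are
independent. A constant per-tone change-prior π implies a geometric prior
over run lengths.

**Recursion.** The run-length posterior is updated exactly (no particle or
variational approximation): growth weights are
w(r+1) ∝ w(r)·(1−π)·p_r(x_t), and the new run-length-0 hypothesis receives
mass exactly π after normalization (the changepoint is placed *after* the
observation it follows, so the datum itself is always scored under the run
it closes). The change probability 1 − P(r_t = t) therefore carries a hazard
baseline of 1 − (1−π)^t before any evidence; this is a property of the model,
not an artifact. At T ≤ 60 the full support is kept; hypotheses beyond the
memory horizon with weight < 10⁻¹² may be pruned (`prune_threshold`), never
the r = t hypothesis the change probability depends on. Belief updates run in
log space with log-sum-exp normalization. The recursion is verified in the
tests against exhaustive enumeration over all changepoint configurations for
T ≤ 8 (agreement < 10⁻⁸).

**Predictive distributions.** Each hypothesis carries Normal–Inverse-Wishart
(NIW) statistics over the overlapping D-tuples inside its (memory-capped)
run window: a window of w tones contributes max(0, w − D + 1) tuples. The
posterior predictive is multivariate Student-t; the scalar prediction for
the next tone is its conditional given the trailing D − 1 *observed* tones.
For a new run the context may lie before the hypothesized changepoint: it
enters only through this conditioning, never through the sufficient
statistics, preserving run independence. Near the sequence start missing
context coordinates are marginalized out. A `plugin_gaussian` switch replaces
the Student-t by a Gaussian at the posterior point estimates (mean, expected
covariance); the default is the full Student-t.

**Perceptual parameters.** Memory m caps the window at the last m tones, so
all hypotheses with r ≥ m share one predictive. Observation noise n (scale
steps) is added as n²·I to the predictive scale matrix *before* conditioning.
Placed there, the predictive variance provably stays ≥ n² for every
hypothesis at every time (adding n² inside the NIW update would not give this
floor); it also reproduces the intended behavior that noise inflates
prediction uncertainty while the statistics themselves are collected
noise-free.

**Prior.** Defaults: μ₀ at the scale midpoint, κ₀ = 1, ν₀ = D + 2 (so the
prior expected covariance equals Λ₀), Λ₀ = σ²·I with σ = (n_steps − 1)/5 —
the stimulus standard deviation implied by the quantization mapping below.
With κ₀ = 1 the prior washes out after a handful of tones; all
hyperparameters are configurable (`PriorHyperparams`). Λ₀ is symmetric
positive-definite by validation, so predictive scatters never go singular
even at n = 0 with empty runs.

**Decision rule.** The yes/no decision compares the *final* change
probability to τ; the model changepoint is the earliest threshold crossing.
Both are reported because a trace can cross τ and fall back below it — the
decision then is "no" although a changepoint exists. Units: changepoints are
0-based tone indices; seconds are index × inter-onset interval.

## Stimulus generators

**Random fractals.** 1/f^β sequences are synthesized spectrally: amplitudes
f^(−β/2) at positive frequencies (zero DC, real Nyquist bin), i.i.d. uniform
phases, inverse real FFT. The periodogram slope of the output recovers −β
within ±0.3 (averaged over 50 instances at length 4096, verified per test).
Sequences are standardized to mean 0, variance 1, then mapped linearly so
±2.5 SD spans the full scale, clipped, and rounded to the nearest step
(`clip_sd` configurable). Change trials standardize and quantize each half
independently, which equalizes mean and variance across the melody so only
higher-order structure changes at the midpoint.

**Markov melodies.** Transitions follow a logistic bump centered on the
previous pitch with P(x_t = x_{t−1}) = 0 and mass ∝ 1/(1 + e^{k·|Δ|})
otherwise: k = 0 is uniform over the 10 non-repeat steps (maximum entropy),
k = 0.7 concentrates on small steps. The printed form of this curve is
ambiguous about the sign of the exponent; the implemented sign is the one
under which mass decreases with step size as the surrounding description
requires. For change trials k ramps linearly across the middle 10 tones
("smooth" transition; the ramp shape is configurable), making the INCR and
DECR schedules exact time-reversals.

**Scales and audio.** Scales are geometric with ratio 2^(1/steps_per_octave),
anchored at the center (behavioral scale: 35 steps, 15/octave, 330 Hz center,
endpoints 150/724 Hz) or at the bottom (EEG scale: 11 semitone steps from
247 Hz to 440 Hz); center- vs bottom-anchoring reproduces each printed range.
Tones are pure sinusoids with squared-cosine on/off ramps, silent between
offset and the next onset, written as 16-bit 44.1 kHz WAV.

## Behavior and fitting

d′ = z(hit) − z(FA) with extreme rates replaced by 1/(2N) and 1 − 1/(2N)
(the correction convention is recorded in the output). Hits are tabulated per
change degree × direction × length, FAs per control entropy level × length;
DECR trials inherit the high-entropy pre-change context, which is how
entropy-driven FA differences surface per direction. For online-response
scoring, a yes before the nominal midpoint of a change trial is counted as a
false alarm.

The sweep evaluates each (m, n, π) once per trial and derives all τ cells
from the stored change-probability endpoints; it is deterministic given the
stimulus seeds. Subject fitting minimizes Euclidean distance between the
subject's and each cell's performance vector — (hit_INCR, hit_DECR,
FA_overall) by default, "overall" (hit, FA) as an alternative — with ties
broken toward parsimony (smallest m, then n), recorded in the fit. Parameter
recovery at desk scale is tested by refitting simulated model-driven
subjects (5% lapse): (m, n) returns within one grid step for ≥ 80% of 20
subjects; recovery of π and τ is not expected and not asserted.

## EEG statistics

**rERP.** Single-trial tone-locked epochs (baseline-subtracted upstream) are
regressed at every time point on LOS and HOS surprisal jointly with an
intercept; because the design matrix is shared across time points the whole
fit is a single least-squares solve. Perfectly collinear or zero-variance
regressors raise a degenerate-design error naming the offender. With centered
regressors the intercept time-course equals the across-trial mean ERP.

**PLV.** Phase per trial is the raw Fourier coefficient at the target
frequency over a window spanning an integer number of cycles (7 tones =
1120 ms = 7 cycles at the 6.25 Hz tone rate); no taper is needed at integer
cycles. PLV is the magnitude of the mean unit phasor: 1 for identical
phases, 0 for phases spread evenly, invariant to per-trial amplitude.
ΔPLV = PLV(after) − PLV(before) around per-trial changepoints, windows
aligned to tone onsets; trials whose windows leave the recording are
excluded and counted. The permutation null re-places one changepoint per
trial uniformly over positions admitting both windows; the p-value is the
two-sided percentile of the observed ΔPLV with add-one smoothing.

## Synthetic data

Simulated subjects answer with the model's decisions at known true
parameters, each response replaced by a fair coin with the lapse probability
(< 0.5 by validation); response times are changepoint seconds. Synthetic EEG
builds tone epochs from ground-truth Gaussian kernels — a baseline bump, a
positive bump at 200 ms scaled by LOS surprisal, a negative bump at 150 ms
scaled by HOS surprisal (latencies/widths configurable) — plus a
stimulus-locked oscillation at the tone rate and white noise; the
melody-locked trial matrix optionally injects a random phase jump at the
per-trial HOS changepoint. The generator's sampling rate defaults to 250 Hz
so the 160-ms inter-onset interval is exactly 40 samples: tone-aligned
windows then hold whole oscillation cycles and phase statistics carry no
rounding bias. These fixtures emulate the *structure* of surprisal-coded
deflections and changepoint phase resets, not cortical dynamics: passing
tests show the statistics recover what was injected, not that real EEG
behaves this way. Overlap of adjacent tone responses, 1/f background
activity, and between-subject kernel variability are deliberately absent.

## Problem sizes and determinism

Every stochastic component takes an explicit seed; stimulus sets record
per-trial seeds in their manifests, and reruns are bit-identical. The test
suite and the acceptance script use a regenerated Experiment-1-style set
(150 trials of 60 tones) for sweep-based checks, 50-instance ensembles for
spectral-slope checks, 8 synthetic subjects for the phase-locking contrast,
and exhaustive enumeration up to T = 8 for the recursion oracle — sizes
chosen so the full chain, including the 40-cell HOS sweep, completes in a
few minutes on one CPU.

## Known limitations

- The exact recursion is O(T²) per trial with T ≤ 60-scale melodies in mind;
  very long sequences would want hypothesis pruning or resolution reduction.
- The d′ surface over (m, n) is stimulus-ensemble dependent; regenerated
  stimulus sets shift peak locations by a grid step or two, and at n = 0 the
  HOS model's d′ grows with memory up to the melody length (the
  unconstrained model acts as an ideal observer), so the surface has no
  interior optimum in m on this grid.
- Surprisal regressors from the LOS and HOS models are correlated by
  construction; the rERP separates them only up to the usual collinear-OLS
  variance inflation, which the tests quantify via standard errors.
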