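"""Stochastic melody generators and change-detection trial composition.

Two families of stochastic pitch sequences are supported:

* **Random-fractal melodies** with a 1/f^beta spectrum. ``beta`` parameterizes
  entropy: ``beta = 0`` is white noise (maximum entropy); entropy decreases as
  ``beta`` grows.  Sequences are synthesized spectrally, standardized to zero
  mean and unit variance, then quantized onto a :class:`~stochtone.scales.PitchScale`.
* **First-order Markov melodies** whose transition distribution is a logistic
  bump centered on the previous pitch, with slope ``k`` parameterizing entropy
  (``k = 0`` is uniform over the non-repeat steps — maximum entropy) and tone
  repetitions excluded by construction.

Change trials concatenate two segments with different entropy; the nominal
changepoint is always the sequence midpoint, and lower-order statistics (mean,
variance) are equalized across the halves so only higher-order temporal
structure changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scales import PitchScale, build_scale

__all__ = [
    "PitchSequence",
    "generate_fractal_sequence",
    "standardize_and_quantize",
    "compose_change_trial",
    "markov_transition",
    "markov_k_schedule",
    "generate_markov_trial",
    "experiment_conditions",
    "generate_experiment",
    "exp1_scale",
    "eeg_scale",
    "sequences_to_manifest",
    "DEFAULT_CLIP_SD",
]

DEFAULT_CLIP_SD = 2.5

#: entropy levels used in the behavioral experiments (spectral slopes)
BETA_LEVELS = (0.0, 1.5, 2.0, 2.5)

#: logistic-slope levels used in the EEG experiment (high / low entropy)
K_HIGH_ENTROPY = 0.0
K_LOW_ENTROPY = 0.7


def exp1_scale() -> PitchScale:
    """The 35-step quasi-semitone behavioral scale centered on 330 Hz."""
    return build_scale(330.0, 15, 35)


def eeg_scale() -> PitchScale:
    """The 11-step semitone EEG scale anchored at 247 Hz."""
    return build_scale(247.0, 12, 11, anchor="bottom")


@dataclass
class PitchSequence:
    """An ordered melody of scale-step pitches plus generation metadata.

    ``pitches`` are integer indices into the generating scale.  ``direction``
    is ``"INCR"`` / ``"DECR"`` for entropy-increasing / -decreasing change
    trials and ``"NONE"`` for controls; ``nominal_changepoint`` is the 0-based
    index of the first tone of the second segment (the trial midpoint) or
    ``None`` for controls.
    """

    pitches: np.ndarray
    entropy_params: dict = field(default_factory=dict)
    nominal_changepoint: int | None = None
    direction: str = "NONE"
    seed: int | None = None
    n_steps: int | None = None
    trial_id: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.pitches = np.asarray(self.pitches, dtype=int)
        if self.n_steps is not None:
            if np.any((self.pitches < 0) | (self.pitches >= self.n_steps)):
                raise ValueError("pitch indices out of scale bounds")
        if self.direction not in ("INCR", "DECR", "NONE"):
            raise ValueError(f"invalid direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.pitches)

    @property
    def is_change(self) -> bool:
        return self.direction != "NONE"


# ---------------------------------------------------------------------------
# random-fractal (1/f^beta) melodies
# ---------------------------------------------------------------------------

def generate_fractal_sequence(beta: float, length: int, seed=None) -> np.ndarray:
    """Generate a real-valued 1/f^beta random-fractal sequence.

    A conjugate-symmetric spectrum is built with amplitude ``f**(-beta/2)`` at
    positive frequencies (zero DC) and i.i.d. uniform random phases, then
    inverse-transformed; the expected log-log periodogram slope of the output
    is ``-beta``.

    Parameters
    ----------
    beta : float
        Spectral slope (>= 0); 0 yields white noise.
    length : int
        Number of samples (>= 2).
    seed : int, numpy Generator, or None
        Source of randomness for the phases.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    n_pos = length // 2 + 1  # rfft bins, including DC and (for even length) Nyquist
    freqs = np.arange(n_pos, dtype=float)
    amp = np.zeros(n_pos)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_pos)
    spectrum = amp * np.exp(1j * phase)
    spectrum[0] = 0.0
    if length % 2 == 0:
        # Nyquist bin of a real signal is real-valued
        spectrum[-1] = amp[-1] * np.cos(phase[-1])
    return np.fft.irfft(spectrum, n=length)


def standardize_and_quantize(
    sequence: np.ndarray,
    scale: PitchScale,
    clip_sd: float = DEFAULT_CLIP_SD,
) -> np.ndarray:
    """Standardize a real-valued sequence and quantize it onto a pitch scale.

    The sequence is shifted/scaled to sample mean 0 and variance 1, then
    linearly mapped so that ``[-clip_sd, +clip_sd]`` standard deviations span
    the full scale; values outside are clipped to the extreme steps, and the
    result is rounded to the nearest step index.

    Returns the integer step indices (not a :class:`PitchSequence`).
    """
    x = np.asarray(sequence, dtype=float)
    if x.size < 2:
        raise ValueError("sequence length must be >= 2")
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate input: zero variance")
    z = (x - x.mean()) / sd
    span = scale.n_steps - 1
    steps = np.rint((z + clip_sd) / (2.0 * clip_sd) * span)
    return np.clip(steps, 0, span).astype(int)


def compose_change_trial(
    beta_first: float,
    beta_second: float,
    length: int,
    seed=None,
    scale: PitchScale | None = None,
    clip_sd: float = DEFAULT_CLIP_SD,
) -> PitchSequence:
    """Compose a change trial from two equal-length fractal segments.

    Each half is generated at its own spectral slope and independently
    standardized and quantized, so mean and variance are equalized across the
    melody and only the higher-order (temporal-dependence) statistics change
    at the midpoint.  Entropy *increases* (INCR) when beta decreases.
    """
    if length % 2 != 0:
        raise ValueError("length must be even (change at the midpoint)")
    if length < 4:
        raise ValueError("length must be >= 4")
    scale = scale or exp1_scale()
    rng = np.random.default_rng(seed)
    halves = []
    for beta in (beta_first, beta_second):
        raw = generate_fractal_sequence(beta, length // 2, rng)
        halves.append(standardize_and_quantize(raw, scale, clip_sd=clip_sd))
    pitches = np.concatenate(halves)
    if beta_second < beta_first:
        direction = "INCR"
    elif beta_second > beta_first:
        direction = "DECR"
    else:
        direction = "NONE"
    return PitchSequence(
        pitches=pitches,
        entropy_params={"beta_first": beta_first, "beta_second": beta_second},
        nominal_changepoint=length // 2 if direction != "NONE" else None,
        direction=direction,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        n_steps=scale.n_steps,
    )


def generate_control_trial(
    beta: float,
    length: int,
    seed=None,
    scale: PitchScale | None = None,
    clip_sd: float = DEFAULT_CLIP_SD,
) -> PitchSequence:
    """A constant-entropy fractal control melody (no change)."""
    scale = scale or exp1_scale()
    raw = generate_fractal_sequence(beta, length, seed)
    pitches = standardize_and_quantize(raw, scale, clip_sd=clip_sd)
    return PitchSequence(
        pitches=pitches,
        entropy_params={"beta_first": beta, "beta_second": beta},
        nominal_changepoint=None,
        direction="NONE",
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        n_steps=scale.n_steps,
    )


# ---------------------------------------------------------------------------
# first-order Markov (logistic) melodies
# ---------------------------------------------------------------------------

def markov_transition(x_prev: int, k: float, scale: PitchScale) -> np.ndarray:
    """Transition distribution over scale steps given the previous pitch.

    Probability is 0 at ``x_prev`` (no repetitions) and proportional to
    ``1 / (1 + exp(k * |x - x_prev|))`` elsewhere: for ``k > 0`` mass decays
    with pitch distance (lower entropy); ``k = 0`` is uniform over the
    remaining steps (maximum entropy).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if not 0 <= x_prev < scale.n_steps:
        raise ValueError("x_prev out of scale bounds")
    steps = np.arange(scale.n_steps)
    dist = np.abs(steps - x_prev).astype(float)
    p = 1.0 / (1.0 + np.exp(k * dist))
    p[x_prev] = 0.0
    return p / p.sum()


def markov_k_schedule(
    direction: str,
    length: int = 50,
    k_low_entropy: float = K_LOW_ENTROPY,
    k_high_entropy: float = K_HIGH_ENTROPY,
    transition_tones: tuple[int, int] = (20, 30),
) -> np.ndarray:
    """Per-tone logistic-slope schedule for one EEG-style trial.

    Returns an array of length ``length``; entry ``t`` is the slope used when
    sampling tone ``t`` from tone ``t-1`` (entry 0 is unused — the first tone
    is uniform).  For change trials ``k`` interpolates linearly over the middle
    tones (0-based indices ``transition_tones[0] .. transition_tones[1] - 1``,
    i.e. tones 21-30 in 1-based counting for the 50-tone default).
    """
    lo, hi = transition_tones
    if not (0 < lo < hi <= length):
        raise ValueError("invalid transition window")
    if direction == "NONE_HIGH":
        return np.full(length, k_high_entropy)
    if direction == "NONE_LOW":
        return np.full(length, k_low_entropy)
    if direction == "INCR":  # low entropy -> high entropy: k decreases
        k_start, k_end = k_low_entropy, k_high_entropy
    elif direction == "DECR":
        k_start, k_end = k_high_entropy, k_low_entropy
    else:
        raise ValueError(f"invalid direction {direction!r}")
    ks = np.empty(length)
    ks[:lo] = k_start
    ks[hi:] = k_end
    # linear ramp across the transition tones, exclusive of the flat endpoints
    ks[lo:hi] = np.linspace(k_start, k_end, hi - lo + 2)[1:-1]
    return ks


def generate_markov_trial(
    direction: str,
    length: int = 50,
    seed=None,
    scale: PitchScale | None = None,
    **schedule_kwargs,
) -> PitchSequence:
    """Sample one EEG-style Markov melody.

    ``direction`` is one of ``INCR``, ``DECR`` (change trials), ``NONE_LOW``,
    ``NONE_HIGH`` (constant-entropy controls).  The first tone is uniform over
    all steps; each subsequent tone is drawn from :func:`markov_transition`
    with the per-tone slope from :func:`markov_k_schedule`.
    """
    scale = scale or eeg_scale()
    ks = markov_k_schedule(direction, length=length, **schedule_kwargs)
    rng = np.random.default_rng(seed)
    steps = np.arange(scale.n_steps)
    pitches = np.empty(length, dtype=int)
    pitches[0] = rng.integers(scale.n_steps)
    for t in range(1, length):
        p = markov_transition(pitches[t - 1], ks[t], scale)
        pitches[t] = rng.choice(steps, p=p)
    is_change = direction in ("INCR", "DECR")
    return PitchSequence(
        pitches=pitches,
        entropy_params={"k_schedule": direction, "k_values": ks},
        nominal_changepoint=length // 2 if is_change else None,
        direction=direction if is_change else "NONE",
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        n_steps=scale.n_steps,
    )


# ---------------------------------------------------------------------------
# experiment definitions
# ---------------------------------------------------------------------------

def experiment_conditions(experiment: str) -> list[dict]:
    """Condition grid for a named experiment.

    ``exp1``: 6 change (3 entropy-change degrees x 2 directions) + 4 control
    entropy levels, 60 tones, 15 trials each — 150 trials.
    ``exp2``: the same degrees/directions crossed with lengths 20/40/60 plus
    4 control levels x 3 lengths, 8 trials each — 240 trials.
    ``eeg``: Markov melodies, 50 tones; 50 INCR + 50 DECR + 25 per control
    entropy level — 150 trials.
    """
    conds: list[dict] = []
    if experiment in ("exp1", "exp2"):
        lengths = [60] if experiment == "exp1" else [20, 40, 60]
        n_change = 15 if experiment == "exp1" else 8
        n_control = 15 if experiment == "exp1" else 8
        for length in lengths:
            for beta in BETA_LEVELS[1:]:  # delta-beta = beta - 0
                conds.append(dict(kind="fractal", beta_first=beta, beta_second=0.0,
                                  direction="INCR", length=length, n_trials=n_change))
                conds.append(dict(kind="fractal", beta_first=0.0, beta_second=beta,
                                  direction="DECR", length=length, n_trials=n_change))
            for beta in BETA_LEVELS:
                conds.append(dict(kind="fractal", beta_first=beta, beta_second=beta,
                                  direction="NONE", length=length, n_trials=n_control))
    elif experiment == "eeg":
        for direction, n in [("INCR", 50), ("DECR", 50), ("NONE_LOW", 25), ("NONE_HIGH", 25)]:
            conds.append(dict(kind="markov", direction=direction, length=50, n_trials=n))
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    for c in conds:
        c["condition"] = _condition_label(c)
    return conds


def _condition_label(c: dict) -> str:
    if c["kind"] == "fractal":
        if c["direction"] == "NONE":
            return f"ctrl_b{c['beta_first']:g}_L{c['length']}"
        return f"{c['direction']}_db{abs(c['beta_first'] - c['beta_second']):g}_L{c['length']}"
    return f"mkv_{c['direction']}"


def generate_experiment(
    experiment: str,
    seed: int = 0,
    scale: PitchScale | None = None,
    trials_per_condition: int | None = None,
) -> list[PitchSequence]:
    """Generate the full stimulus set for a named experiment.

    Per-trial seeds are spawned deterministically from ``seed``; they are
    recorded on each :class:`PitchSequence` (and in the manifest) so any trial
    can be regenerated in isolation.  ``trials_per_condition`` overrides the
    experiment's nominal trial counts (useful for reduced test sets).
    """
    conds = experiment_conditions(experiment)
    root = np.random.SeedSequence(seed)
    sequences: list[PitchSequence] = []
    trial_idx = 0
    for cond in conds:
        n_trials = trials_per_condition or cond["n_trials"]
        for _ in range(n_trials):
            trial_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
            if cond["kind"] == "fractal":
                if cond["direction"] == "NONE":
                    seq = generate_control_trial(cond["beta_first"], cond["length"],
                                                 seed=trial_seed, scale=scale)
                else:
                    seq = compose_change_trial(cond["beta_first"], cond["beta_second"],
                                               cond["length"], seed=trial_seed, scale=scale)
            else:
                seq = generate_markov_trial(cond["direction"], cond["length"],
                                            seed=trial_seed, scale=scale)
            seq.trial_id = f"{experiment}_{trial_idx:04d}"
            seq.condition = cond["condition"]
            sequences.append(seq)
            trial_idx += 1
    return sequences


def sequences_to_manifest(sequences: Sequence[PitchSequence]) -> pd.DataFrame:
    """Tabulate trial metadata as a manifest DataFrame (CSV-ready)."""
    rows = []
    for seq in sequences:
        ep = seq.entropy_params
        rows.append(dict(
            trial_id=seq.trial_id,
            condition=seq.condition,
            direction=seq.direction,
            is_change=seq.is_change,
            beta_first=ep.get("beta_first"),
            beta_second=ep.get("beta_second"),
            k_schedule=ep.get("k_schedule"),
            length=len(seq),
            seed=seq.seed,
            nominal_changepoint=seq.nominal_changepoint,
        ))
    return pd.DataFrame(rows)
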