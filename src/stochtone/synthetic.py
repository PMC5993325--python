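"""Synthetic fixtures: model-driven subjects and surprisal-coded EEG.

These generators make the full analysis chain testable without human data.
A *simulated subject* answers trials with the change decisions of the model
at known true parameters, contaminated by a lapse rate; re-fitting those
responses tests parameter recovery.  *Synthetic EEG* builds tone-locked
epochs as a baseline kernel plus surprisal-scaled deflection kernels (a
P2-latency positivity for LOS surprisal, an MMN-latency negativity for HOS
surprisal), a stimulus-locked oscillation at the tone rate with an optional
phase reset at the per-trial changepoint, and white noise.  The generator
emulates the *structure* of the reported neural effects, not cortical
dynamics; ground-truth kernels are returned for assertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg import EpochMatrix
from .model import ModelParams, ModelTrace, run_model
from .stimuli import PitchSequence

__all__ = [
    "SyntheticSubjectSpec", "simulate_subject",
    "SyntheticEegSpec", "SyntheticEeg", "simulate_eeg", "gaussian_kernel",
]


# ---------------------------------------------------------------------------
# simulated subjects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSubjectSpec:
    """A model-driven responder: true parameters plus a lapse rate.

    With probability ``lapse_rate`` a trial's response is replaced by a fair
    coin flip (must stay below 0.5, else responses are mostly noise).
    """

    params: ModelParams
    lapse_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5)")


def simulate_subject(
    spec: SyntheticSubjectSpec,
    sequences: list[PitchSequence],
    ioi: float = 0.175,
    decisions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Response table of a simulated subject on a stimulus set.

    Responses are the model's change decisions under the true parameters,
    each independently replaced by a random response with probability
    ``lapse_rate``.  Response times are the model changepoint converted to
    seconds (tone index x IOI) where a changepoint exists.  Precomputed
    per-trial ``decisions`` (e.g. from a sweep) can be supplied to skip the
    model runs; changepoint RTs are then omitted.
    """
    rng = np.random.default_rng(spec.seed)
    if decisions is None:
        traces = [run_model(seq, spec.params, keep_beliefs=False) for seq in sequences]
        dec = np.array([tr.decision for tr in traces])
        rts = [None if tr.changepoint is None else tr.changepoint * ioi for tr in traces]
    else:
        dec = np.asarray(decisions, dtype=bool).copy()
        rts = [None] * len(sequences)
    lapse = rng.random(dec.size) < spec.lapse_rate
    dec[lapse] = rng.random(lapse.sum()) < 0.5
    return pd.DataFrame({
        "trial_id": [s.trial_id for s in sequences],
        "response": dec,
        "response_time": rts,
    })


# ---------------------------------------------------------------------------
# synthetic EEG
# ---------------------------------------------------------------------------

def gaussian_kernel(times: np.ndarray, center: float, width: float, amplitude: float) -> np.ndarray:
    """A Gaussian deflection kernel on a time axis (seconds)."""
    return amplitude * np.exp(-0.5 * ((times - center) / width) ** 2)


@dataclass(frozen=True)
class SyntheticEegSpec:
    """Generation parameters for synthetic tone-locked EEG.

    Kernels are Gaussian bumps: the baseline ERP, a positive bump at P2
    latency scaled by LOS surprisal (``gain_L``), and a negative bump at MMN
    latency scaled by HOS surprisal (``gain_H``).  ``osc_amplitude`` adds a
    stimulus-locked sinusoid at the tone rate; with ``phase_reset`` the
    oscillation jumps to a random phase at the trial's changepoint.

    The default sampling rate makes the 160-ms inter-onset interval an integer
    number of samples (40), so tone-aligned analysis windows contain exactly
    whole oscillation cycles and phase statistics carry no rounding artifact.
    """

    sfreq: float = 250.0
    ioi: float = 0.160
    epoch_window: tuple[float, float] = (-0.05, 0.35)
    baseline_amp: float = 1.0
    baseline_latency: float = 0.10
    gain_L: float = 0.5
    gain_L_latency: float = 0.20
    gain_H: float = -0.5
    gain_H_latency: float = 0.15
    kernel_width: float = 0.03
    osc_amplitude: float = 0.0
    phase_reset: bool = False
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("invalid epoch window")


@dataclass
class SyntheticEeg:
    """Synthetic EEG with ground truth for assertions."""

    tone_epochs: EpochMatrix                 # tone-locked, for rERP
    trial_matrix: np.ndarray                 # melody-locked (trials x samples), for PLV
    trial_times: np.ndarray
    changepoint_tone: np.ndarray             # per-trial HOS changepoint (NaN if none)
    kernels: dict = field(default_factory=dict)
    spec: SyntheticEegSpec = None


def simulate_eeg(
    spec: SyntheticEegSpec,
    traces_los: list[ModelTrace],
    traces_hos: list[ModelTrace],
) -> SyntheticEeg:
    """Generate synthetic EEG coded by model surprisal.

    ``traces_los`` / ``traces_hos`` supply per-tone surprisal regressors
    (S_L, S_H) and the per-trial HOS changepoint.  Tone epochs are built
    directly from the ground-truth kernels (plus the tone-rate oscillation
    and noise); the melody-locked matrix carries the oscillation with the
    optional phase reset for changepoint-locked phase analyses.
    """
    rng = np.random.default_rng(spec.seed)
    sf = spec.sfreq
    t0, t1 = spec.epoch_window
    etimes = np.arange(round(t0 * sf), round(t1 * sf)) / sf
    k0 = gaussian_kernel(etimes, spec.baseline_latency, spec.kernel_width, spec.baseline_amp)
    kL = gaussian_kernel(etimes, spec.gain_L_latency, spec.kernel_width, spec.gain_L)
    kH = gaussian_kernel(etimes, spec.gain_H_latency, spec.kernel_width, spec.gain_H)
    tone_rate = 1.0 / spec.ioi

    epochs, regs = [], []
    trial_rows, cps = [], []
    n_tones = len(traces_los[0])
    n_samp = int(round(n_tones * spec.ioi * sf))
    ttimes = np.arange(n_samp) / sf
    for i, (trl, trh) in enumerate(zip(traces_los, traces_hos)):
        sl, sh = trl.surprisal, trh.surprisal
        cp = trh.changepoint
        cps.append(np.nan if cp is None else cp)
        # tone-locked epochs from the ground-truth kernels
        for tone in range(n_tones):
            y = (k0 + sl[tone] * kL + sh[tone] * kH
                 + spec.osc_amplitude * np.cos(2 * np.pi * tone_rate * (tone * spec.ioi + etimes)))
            if spec.noise_sd > 0:
                y = y + rng.normal(0, spec.noise_sd, etimes.size)
            epochs.append(y)
            regs.append(dict(trial=i, tone=tone, S_L=sl[tone], S_H=sh[tone]))
        # melody-locked oscillation for phase analyses
        y = spec.osc_amplitude * np.cos(2 * np.pi * tone_rate * ttimes)
        if spec.phase_reset and cp is not None:
            jump = rng.uniform(0, 2 * np.pi)
            reset = ttimes >= cp * spec.ioi
            y = np.where(reset,
                         spec.osc_amplitude * np.cos(2 * np.pi * tone_rate * ttimes + jump),
                         y)
        if spec.noise_sd > 0:
            y = y + rng.normal(0, spec.noise_sd, n_samp)
        trial_rows.append(y)

    tone_epochs = EpochMatrix(
        data=np.array(epochs),
        times=etimes,
        sfreq=sf,
        regressors=pd.DataFrame(regs)[["S_L", "S_H"]],
        metadata=pd.DataFrame(regs)[["trial", "tone"]],
    )
    return SyntheticEeg(
        tone_epochs=tone_epochs,
        trial_matrix=np.array(trial_rows),
        trial_times=ttimes,
        changepoint_tone=np.array(cps, dtype=float),
        kernels={"baseline": k0, "L": kL, "H": kH, "times": etimes},
        spec=spec,
    )
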