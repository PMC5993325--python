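"""Pure-tone melody synthesis and 16-bit WAV I/O.

Each tone is a sinusoid at its scale frequency, gated by squared-cosine
onset/offset ramps, placed at a fixed inter-onset interval.  Defaults follow
the behavioral experiments (150 ms tones, 10 ms ramps, 175 ms IOI); the EEG
experiment used 125 ms tones at 160 ms IOI (a 6.25 Hz presentation rate).
"""

from __future__ import annotations

import wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .scales import PitchScale
from .stimuli import PitchSequence

__all__ = ["ToneSynthesisSpec", "synthesize_audio", "write_wav", "read_wav",
           "EXP1_SYNTHESIS", "EEG_SYNTHESIS"]


@dataclass(frozen=True)
class ToneSynthesisSpec:
    """Timing and sampling parameters for melody synthesis (seconds / Hz)."""

    tone_duration: float = 0.150
    onset_offset_ramp: float = 0.010
    inter_onset_interval: float = 0.175
    sample_rate: int = 44100

    def __post_init__(self) -> None:
        if self.tone_duration <= 0 or self.inter_onset_interval <= 0:
            raise ValueError("durations must be positive")
        if self.onset_offset_ramp > self.tone_duration / 2:
            raise ValueError("ramp must be <= half the tone duration")
        if self.tone_duration > self.inter_onset_interval:
            raise ValueError("tone duration must be <= inter-onset interval")

    @property
    def tone_rate_hz(self) -> float:
        return 1.0 / self.inter_onset_interval


EXP1_SYNTHESIS = ToneSynthesisSpec()
EEG_SYNTHESIS = ToneSynthesisSpec(tone_duration=0.125, inter_onset_interval=0.160)


def _tone(freq: float, spec: ToneSynthesisSpec, peak: float) -> np.ndarray:
    sr = spec.sample_rate
    n = round(spec.tone_duration * sr)
    t = np.arange(n) / sr
    y = peak * np.sin(2 * np.pi * freq * t)
    n_ramp = round(spec.onset_offset_ramp * sr)
    if n_ramp > 0:
        # squared-cosine (raised-cosine) on/off gates
        ramp = np.sin(np.linspace(0, np.pi / 2, n_ramp)) ** 2
        y[:n_ramp] *= ramp
        y[-n_ramp:] *= ramp[::-1]
    return y


def synthesize_audio(
    seq: PitchSequence,
    scale: PitchScale,
    spec: ToneSynthesisSpec = EXP1_SYNTHESIS,
    peak: float = 0.9,
) -> np.ndarray:
    """Render a pitch sequence to a mono waveform (float, |amplitude| <= 1).

    The waveform spans ``(n_tones - 1) * IOI + tone_duration`` seconds; the
    gap between tone offset and the next onset is silent.
    """
    if not 0 < peak <= 1:
        raise ValueError("peak must be in (0, 1]")
    freqs = scale.step_to_hz(seq.pitches)
    if np.max(freqs) >= spec.sample_rate / 2:
        raise ValueError("sample rate too low for the highest scale frequency (Nyquist)")
    sr = spec.sample_rate
    hop = round(spec.inter_onset_interval * sr)
    n_tone = round(spec.tone_duration * sr)
    total = (len(seq) - 1) * hop + n_tone
    out = np.zeros(total)
    for i, f in enumerate(np.atleast_1d(freqs)):
        out[i * hop : i * hop + n_tone] += _tone(float(f), spec, peak)
    return out


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int = 44100) -> None:
    """Write a mono float waveform as 16-bit PCM WAV."""
    data = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    pcm = (data * 32767.0).round().astype("<i2")
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(int(sample_rate))
        w.writeframes(pcm.tobytes())


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono 16-bit PCM WAV back to float in [-1, 1]."""
    with wave.open(str(path), "rb") as w:
        if w.getsampwidth() != 2 or w.getnchannels() != 1:
            raise ValueError("expected mono 16-bit PCM")
        sr = w.getframerate()
        pcm = np.frombuffer(w.readframes(w.getnframes()), dtype="<i2")
    return pcm.astype(float) / 32767.0, sr
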