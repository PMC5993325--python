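"""Logarithmic pitch scales for tone-sequence stimuli.

A :class:`PitchScale` maps integer scale steps to frequencies in Hz with a
fixed ratio of ``2**(1/steps_per_octave)`` between adjacent steps.  Scales may
be anchored at their center step (the behavioral quasi-semitone scale: 35
steps, 15 per octave, centered on 330 Hz) or at their bottom step (the EEG
semitone scale: 11 steps from 247 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PitchScale", "build_scale"]


@dataclass(frozen=True)
class PitchScale:
    """A centered logarithmic frequency scale.

    Attributes
    ----------
    center_hz : float
        Frequency of the middle step ``(n_steps - 1) / 2`` (a half-step
        position when ``n_steps`` is even).
    steps_per_octave : int
        Number of scale steps per octave (doubling of frequency).
    n_steps : int
        Total number of steps; valid step indices are ``0 .. n_steps - 1``.
    """

    center_hz: float
    steps_per_octave: int
    n_steps: int
    frequencies: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.center_hz <= 0:
            raise ValueError(f"center_hz must be positive, got {self.center_hz}")
        if self.steps_per_octave < 1:
            raise ValueError("steps_per_octave must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        steps = np.arange(self.n_steps)
        freqs = self.center_hz * 2.0 ** ((steps - (self.n_steps - 1) / 2.0) / self.steps_per_octave)
        object.__setattr__(self, "frequencies", freqs)

    def step_to_hz(self, step) -> np.ndarray | float:
        """Frequency in Hz of one or more scale steps."""
        step = np.asarray(step)
        if np.any((step < 0) | (step >= self.n_steps)):
            raise ValueError("step index out of scale bounds")
        out = self.frequencies[step]
        return float(out) if out.ndim == 0 else out

    @property
    def midpoint_step(self) -> float:
        return (self.n_steps - 1) / 2.0


def build_scale(
    anchor_hz: float,
    steps_per_octave: int,
    n_steps: int,
    anchor: str = "center",
) -> PitchScale:
    """Build a pitch scale anchored at its center or bottom frequency.

    Parameters
    ----------
    anchor_hz : float
        Frequency of the anchor step: the middle step for ``anchor="center"``,
        step 0 for ``anchor="bottom"``.
    steps_per_octave : int
        Steps per octave; 15 gives the quasi-semitone behavioral scale, 12 a
        true semitone scale.
    n_steps : int
        Number of steps on the scale.
    anchor : {"center", "bottom"}
        Anchoring convention.

    Examples
    --------
    >>> s = build_scale(330.0, 15, 35)
    >>> round(s.frequencies[-1])
    724
    >>> round(build_scale(247.0, 12, 11, anchor="bottom").frequencies[-1])
    440
    """
    if anchor_hz <= 0:
        raise ValueError("anchor frequency must be positive")
    if anchor == "center":
        center = float(anchor_hz)
    elif anchor == "bottom":
        center = float(anchor_hz) * 2.0 ** (((n_steps - 1) / 2.0) / steps_per_octave)
    else:
        raise ValueError(f"unknown anchor {anchor!r}; use 'center' or 'bottom'")
    return PitchScale(center_hz=center, steps_per_octave=steps_per_octave, n_steps=n_steps)
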