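"""Model-guided EEG statistics: surprisal regression ERPs and phase-locking.

Two analyses anchor single-trial neural responses to the statistics of each
stochastic stimulus as interpreted by the change-detection model:

* **rERP** — at every time point, single-trial tone-locked ERPs are regressed
  jointly on LOS and HOS surprisal: ``y_i(t) = b0(t) + S_L*bL(t) + S_H*bH(t)
  + e_i(t)``.  The intercept time-course is the baseline ERP; each slope
  time-course is the differential response per unit surprisal.
* **PLV / delta-PLV** — phase agreement across trials at the tone presentation
  rate (6.25 Hz by default), measured as the magnitude of the mean unit
  phasor of the Fourier coefficient in an integer-cycle window.  delta-PLV
  contrasts 7-tone windows after vs before a per-trial changepoint; a
  permutation null re-places the changepoints uniformly at random.

This module is electrode-agnostic: it consumes one (already averaged)
channel, tone- or melody-locked, with preprocessing done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "EpochMatrix", "RerpResult", "PlvResult", "NullDeltaPlv",
    "rerp_fit", "outlier_filter", "plv", "phasors",
    "delta_plv_at_changepoints", "null_delta_plv", "SurprisalRERP",
]


@dataclass
class EpochMatrix:
    """Tone- or changepoint-locked single-trial responses with regressors.

    ``data``: (n_trials, n_times) amplitudes; ``times``: seconds relative to
    the lock event (uniform); ``sfreq``: sampling rate in Hz; ``regressors``:
    per-trial DataFrame with at least ``S_L`` and ``S_H`` columns (surprisal
    in nats) when used for regression.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    regressors: pd.DataFrame | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape[1] != self.times.size:
            raise ValueError("data and time axis length mismatch")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0]):
                raise ValueError("time axis must be uniform")
        if self.regressors is not None and len(self.regressors) != self.n_trials:
            raise ValueError("regressors must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochMatrix":
        mask = np.asarray(mask)
        return EpochMatrix(
            data=self.data[mask],
            times=self.times,
            sfreq=self.sfreq,
            regressors=None if self.regressors is None else self.regressors.iloc[mask].reset_index(drop=True),
            metadata=None if self.metadata is None else self.metadata.iloc[mask].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# regression ERP
# ---------------------------------------------------------------------------

@dataclass
class RerpResult:
    """Per-time-point regression coefficients and residual variance."""

    times: np.ndarray
    beta0: np.ndarray
    betaL: np.ndarray
    betaH: np.ndarray
    resid_var: np.ndarray


def rerp_fit(epochs: EpochMatrix) -> RerpResult:
    """Per-time-point OLS of single-trial ERPs on LOS and HOS surprisal.

    Both regressors enter jointly with an intercept; the design is shared
    across time points, so the whole fit is one least-squares solve.  Epochs
    are assumed baseline-subtracted upstream (50-ms pre-onset window).
    """
    if epochs.regressors is None or not {"S_L", "S_H"} <= set(epochs.regressors.columns):
        raise ValueError("epochs.regressors must contain S_L and S_H columns")
    if epochs.n_trials < 3:
        raise ValueError("need at least 3 trials to fit intercept + 2 slopes")
    sl = epochs.regressors["S_L"].to_numpy(dtype=float)
    sh = epochs.regressors["S_H"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(sl)) and np.all(np.isfinite(sh))):
        raise ValueError("regressors must be finite")
    for name, reg in (("S_L", sl), ("S_H", sh)):
        if np.ptp(reg) == 0:
            raise ValueError(f"degenerate design: regressor {name} has zero variance")
    r = np.corrcoef(sl, sh)[0, 1]
    if np.abs(r) > 1 - 1e-12:
        raise ValueError("degenerate design: S_L and S_H are perfectly collinear")
    X = np.column_stack([np.ones_like(sl), sl, sh])
    coef, _, _, _ = np.linalg.lstsq(X, epochs.data, rcond=None)
    resid = epochs.data - X @ coef
    dof = max(epochs.n_trials - 3, 1)
    return RerpResult(
        times=epochs.times,
        beta0=coef[0], betaL=coef[1], betaH=coef[2],
        resid_var=(resid**2).sum(axis=0) / dof,
    )


class SurprisalRERP(BaseEstimator):
    """scikit-learn facade over :func:`rerp_fit`.

    ``fit(epochs)`` exposes ``intercept_`` (baseline ERP), ``coef_L_`` and
    ``coef_H_`` (surprisal slope time-courses), and ``resid_var_``.
    """

    def fit(self, X: EpochMatrix, y=None):
        res = rerp_fit(X)
        self.times_ = res.times
        self.intercept_ = res.beta0
        self.coef_L_ = res.betaL
        self.coef_H_ = res.betaH
        self.resid_var_ = res.resid_var
        return self

    def predict(self, regressors: pd.DataFrame) -> np.ndarray:
        """Fitted ERP time-courses for given (S_L, S_H) rows."""
        sl = regressors["S_L"].to_numpy(dtype=float)[:, None]
        sh = regressors["S_H"].to_numpy(dtype=float)[:, None]
        return self.intercept_[None, :] + sl * self.coef_L_[None, :] + sh * self.coef_H_[None, :]


def outlier_filter(epochs: EpochMatrix, sd_threshold: float = 3.0) -> EpochMatrix:
    """Drop trials whose peak amplitude exceeds ``sd_threshold`` SDs from the mean.

    The per-trial statistic is the peak absolute amplitude; trials beyond
    ``mean + sd_threshold * sd`` of that statistic across trials are removed.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    peak = np.abs(epochs.data).max(axis=1)
    keep = peak <= peak.mean() + sd_threshold * peak.std()
    if not keep.any():
        raise ValueError("outlier filter removed every trial")
    return epochs.select(keep)


# ---------------------------------------------------------------------------
# phase-locking value
# ---------------------------------------------------------------------------

def phasors(data: np.ndarray, sfreq: float, freq: float) -> np.ndarray:
    """Complex Fourier coefficient of each trial at ``freq`` (no taper).

    The window should span an integer number of cycles of ``freq`` to avoid
    leakage; callers cutting tone-rate windows get this for free.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if freq > sfreq / 2:
        raise ValueError("frequency above Nyquist")
    n = data.shape[1]
    t = np.arange(n) / sfreq
    kernel = np.exp(-2j * np.pi * freq * t)
    return data @ kernel


def plv(epochs, sfreq: float | None = None, freq: float = 6.25) -> float:
    """Phase-locking value: magnitude of the mean unit phasor across trials.

    ``epochs`` may be an :class:`EpochMatrix` or a raw (n_trials, n_times)
    array with ``sfreq`` given.  PLV is 1 for identical phases, 0 for phases
    spread uniformly on the circle, and invariant to per-trial amplitude.
    """
    if isinstance(epochs, EpochMatrix):
        data, sfreq = epochs.data, epochs.sfreq
    else:
        data = np.atleast_2d(np.asarray(epochs, dtype=float))
        if sfreq is None:
            raise ValueError("sfreq required for raw arrays")
    if data.shape[0] < 2:
        raise ValueError("PLV needs at least 2 trials")
    if data.shape[1] < sfreq / freq:
        raise ValueError("window shorter than one cycle of the target frequency")
    ph = phasors(data, sfreq, freq)
    mag = np.abs(ph)
    ok = mag > 0
    if not ok.any():
        raise ValueError("all phasors have zero magnitude")
    return float(np.abs(np.mean(ph[ok] / mag[ok])))


@dataclass
class PlvResult:
    """Pre/post-changepoint phase locking and their difference."""

    plv_before: float
    plv_after: float
    n_trials: int
    window_tones: int
    freq: float
    null_mean: float | None = None
    null_quantiles: tuple | None = None
    n_permutations: int = 0
    p_value: float | None = None

    @property
    def delta_plv(self) -> float:
        return self.plv_after - self.plv_before


def _changepoint_windows(
    data: np.ndarray,
    sfreq: float,
    ioi: float,
    changepoint_tone: np.ndarray,
    window_tones: int,
):
    """Cut tone-onset-aligned windows before/after per-trial changepoints.

    Returns (before, after, kept_index); trials whose windows fall outside
    the recording are excluded.
    """
    n_trials, n_samp = data.shape
    win = int(round(window_tones * ioi * sfreq))
    before, after, kept = [], [], []
    for i in range(n_trials):
        cp = changepoint_tone[i]
        if cp is None or (isinstance(cp, float) and np.isnan(cp)):
            continue
        start = int(round((cp - window_tones) * ioi * sfreq))
        mid = int(round(cp * ioi * sfreq))
        if start < 0 or mid + win > n_samp:
            continue
        before.append(data[i, start : start + win])
        after.append(data[i, mid : mid + win])
        kept.append(i)
    return np.array(before), np.array(after), np.array(kept, dtype=int)


def delta_plv_at_changepoints(
    data: np.ndarray,
    sfreq: float,
    changepoint_tone,
    ioi: float = 0.160,
    freq: float = 6.25,
    window_tones: int = 7,
    include=None,
) -> PlvResult:
    """delta-PLV = PLV(after) - PLV(before) at per-trial changepoints.

    ``data`` is a melody-locked (n_trials, n_samples) matrix; time zero is the
    first tone onset.  Windows are ``window_tones`` tones long (1120 ms at the
    EEG tone rate — 7 cycles of 6.25 Hz), aligned to tone onsets on either
    side of each trial's changepoint.  ``include`` masks trials (e.g. change
    trials correctly detected by both listener and model); trials whose
    windows exceed the recording are excluded and counted out of ``n_trials``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    cps = np.asarray(
        [np.nan if c is None else float(c) for c in np.atleast_1d(changepoint_tone)])
    if include is not None:
        cps = np.where(np.asarray(include, dtype=bool), cps, np.nan)
    before, after, kept = _changepoint_windows(data, sfreq, ioi, cps, window_tones)
    if kept.size < 2:
        raise ValueError("fewer than 2 trials provide full pre/post windows")
    return PlvResult(
        plv_before=plv(before, sfreq, freq),
        plv_after=plv(after, sfreq, freq),
        n_trials=int(kept.size),
        window_tones=window_tones,
        freq=freq,
    )


@dataclass
class NullDeltaPlv:
    """Permutation null for delta-PLV under random changepoint placement."""

    null: np.ndarray
    observed: float | None
    p_value: float | None

    @property
    def mean(self) -> float:
        return float(self.null.mean())

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.null, q)


def null_delta_plv(
    data: np.ndarray,
    sfreq: float,
    n_tones: int,
    ioi: float = 0.160,
    freq: float = 6.25,
    window_tones: int = 7,
    n_perm: int = 1000,
    seed=None,
    observed: float | None = None,
) -> NullDeltaPlv:
    """Empirical null of delta-PLV with changepoints re-placed uniformly.

    Each permutation samples one changepoint per trial uniformly over the tone
    positions admitting both windows, then computes delta-PLV.  The two-sided
    percentile p-value of ``observed`` is reported when given.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    lo, hi = window_tones, n_tones - window_tones
    if hi < lo:
        raise ValueError("melody too short for any valid changepoint placement")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        cps = rng.integers(lo, hi + 1, size=data.shape[0]).astype(float)
        res = delta_plv_at_changepoints(data, sfreq, cps, ioi=ioi, freq=freq,
                                        window_tones=window_tones)
        null[p] = res.delta_plv
    p_value = None
    if observed is not None:
        # two-sided percentile p-value with add-one smoothing
        more_extreme = np.sum(np.abs(null - null.mean()) >= abs(observed - null.mean()))
        p_value = float((more_extreme + 1) / (n_perm + 1))
    return NullDeltaPlv(null=null, observed=observed, p_value=p_value)
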