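"""Signal-detection analysis of change-detection responses.

Hit and false-alarm rates are tabulated per condition cell (change degree x
direction x length for hits; pre-change entropy level x length for FAs) and
summarized as equal-variance sensitivity d' = z(hit) - z(FA).  Extreme rates
(0 or 1) are corrected by the 1/(2N) convention before the z-transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "dprime", "correct_extreme_rate", "PerformancePoint", "PerformanceSummary",
    "performance_by_condition", "roc_coverage", "bootstrap_ci",
    "responses_with_rt_to_decisions",
]


def correct_extreme_rate(rate: float, n: int) -> float:
    """Replace rates of 0 and 1 by 1/(2N) and 1 - 1/(2N)."""
    if n < 1:
        raise ValueError("count must be >= 1")
    if rate <= 0.0:
        return 1.0 / (2.0 * n)
    if rate >= 1.0:
        return 1.0 - 1.0 / (2.0 * n)
    return float(rate)


def dprime(hit_rate: float, fa_rate: float, n_signal: int, n_noise: int) -> float:
    """Equal-variance signal-detection sensitivity.

    ``d' = z(hit) - z(FA)`` with extreme rates corrected by the 1/(2N) rule;
    0 is chance, higher is better detection.
    """
    if not (0 <= hit_rate <= 1 and 0 <= fa_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    h = correct_extreme_rate(hit_rate, n_signal)
    f = correct_extreme_rate(fa_rate, n_noise)
    return float(norm.ppf(h) - norm.ppf(f))


@dataclass(frozen=True)
class PerformancePoint:
    """One operating point in ROC space, with per-direction detail."""

    hit_rate: float
    fa_rate: float
    d_prime: float
    hit_incr: float = np.nan
    hit_decr: float = np.nan
    n_signal: int = 0
    n_noise: int = 0

    def vector(self, kind: str = "by_direction") -> np.ndarray:
        """Performance vector for subject-model distance computations."""
        if kind == "by_direction":
            return np.array([self.hit_incr, self.hit_decr, self.fa_rate])
        if kind == "overall":
            return np.array([self.hit_rate, self.fa_rate])
        raise ValueError(f"unknown vector kind {kind!r}")


@dataclass
class PerformanceSummary:
    """Cellwise and overall detection performance for one response table."""

    overall: PerformancePoint
    hits_by_cell: pd.DataFrame    # per (delta_beta | schedule, direction, length)
    fas_by_cell: pd.DataFrame     # per (entropy level, length)
    correction: str = "1/(2N)"


def _join(responses: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    if responses["trial_id"].duplicated().any():
        raise ValueError("duplicate trial_id in responses")
    merged = responses.merge(manifest, on="trial_id", how="left", validate="1:1")
    if merged["is_change"].isna().any():
        missing = merged.loc[merged["is_change"].isna(), "trial_id"].tolist()[:5]
        raise ValueError(f"responses contain trial ids absent from manifest: {missing}")
    return merged


def performance_by_condition(
    responses: pd.DataFrame,
    manifest: pd.DataFrame,
) -> PerformanceSummary:
    """Compute hit/FA rates per condition cell and overall d'.

    ``responses`` needs columns ``trial_id`` and ``response`` (boolean yes/no);
    ``manifest`` is the stimulus manifest (see
    :func:`stochtone.stimuli.sequences_to_manifest`).  Hits are grouped by
    change degree and direction (and length); FAs by the control melody's
    entropy level (and length).  DECR hit cells inherit the pre-change
    entropy context beta=0, so entropy-driven FA differences surface per
    direction in d' but not in hit rate.
    """
    df = _join(responses, manifest)
    df["response"] = df["response"].astype(bool)

    change = df[df["is_change"]]
    control = df[~df["is_change"]]
    if "beta_first" in df.columns and df["beta_first"].notna().any():
        change = change.assign(
            degree=(change["beta_first"] - change["beta_second"]).abs())
        control = control.assign(level=control["beta_first"])
    else:  # Markov stimuli: degree is categorical, level from the schedule
        change = change.assign(degree="k")
        control = control.assign(
            level=control["condition"].str.replace("mkv_", "", regex=False))

    hits = (change.groupby(["degree", "direction", "length"], observed=True)["response"]
            .agg(hit_rate="mean", n="size").reset_index())
    fas = (control.groupby(["level", "length"], observed=True)["response"]
           .agg(fa_rate="mean", n="size").reset_index())

    n_signal, n_noise = len(change), len(control)
    hit = change["response"].mean() if n_signal else np.nan
    fa = control["response"].mean() if n_noise else np.nan
    by_dir = change.groupby("direction")["response"].mean()
    overall = PerformancePoint(
        hit_rate=float(hit), fa_rate=float(fa),
        d_prime=dprime(hit, fa, n_signal, n_noise) if n_signal and n_noise else np.nan,
        hit_incr=float(by_dir.get("INCR", np.nan)),
        hit_decr=float(by_dir.get("DECR", np.nan)),
        n_signal=n_signal, n_noise=n_noise,
    )
    return PerformanceSummary(overall=overall, hits_by_cell=hits, fas_by_cell=fas)


def responses_with_rt_to_decisions(
    responses: pd.DataFrame,
    manifest: pd.DataFrame,
    ioi: float = 0.175,
) -> pd.DataFrame:
    """Reclassify online (response-time) yes responses for scoring.

    A yes response whose time falls before the nominal changepoint of a change
    trial counts as a false alarm rather than a hit: the trial is scored as a
    control with ``response=True`` by flipping ``is_change`` off for it.
    Returns a copy of the manifest with adjusted ``is_change`` for scoring
    plus the boolean responses.
    """
    df = _join(responses, manifest)
    early = (
        df["is_change"]
        & df["response"].astype(bool)
        & df["response_time"].notna()
        & (df["response_time"] < df["nominal_changepoint"] * ioi)
    )
    out = df.copy()
    out.loc[early, "is_change"] = False
    return out


def roc_coverage(points, grid_resolution: int = 50):
    """Occupancy of a set of performance points over discretized ROC space.

    ``points`` is an iterable of :class:`PerformancePoint` or (fa, hit) pairs.
    Returns ``(occupancy, ceiling_d_prime)`` where ``occupancy`` is a boolean
    ``(grid_resolution, grid_resolution)`` array indexed [fa_bin, hit_bin].
    """
    pts = []
    for p in points:
        if isinstance(p, PerformancePoint):
            pts.append((p.fa_rate, p.hit_rate, p.d_prime))
        else:
            fa, hit = p
            pts.append((fa, hit, dprime(hit, fa, 10**6, 10**6)))
    if not pts:
        raise ValueError("at least one performance point required")
    occ = np.zeros((grid_resolution, grid_resolution), dtype=bool)
    for fa, hit, _ in pts:
        i = min(int(fa * grid_resolution), grid_resolution - 1)
        j = min(int(hit * grid_resolution), grid_resolution - 1)
        occ[i, j] = True
    ceiling = float(max(d for _, _, d in pts))
    return occ, ceiling


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed=None,
    statistic=np.mean,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for a statistic of ``values``."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    stats = statistic(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
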