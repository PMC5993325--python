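"""Parameter sweeps and behavior-matched model fitting.

Model behavior is explored by a grid sweep over the four model parameters
{m, n, pi, tau}.  For each (m, n, pi) the detector is run once per trial; the
threshold tau only gates the resulting change-probability trace, so all tau
values share the same model runs.  Subjects are fit by minimum Euclidean
distance between model and subject performance vectors (per-direction hit
rates plus overall FA rate by default), with ties broken toward parsimony
(smallest m, then smallest n).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .behavior import PerformancePoint, performance_by_condition
from .model import ModelParams, PriorHyperparams, run_model
from .stimuli import PitchSequence, sequences_to_manifest

__all__ = ["SweepGrid", "default_grid", "sweep", "SubjectFit", "fit_subject",
           "changepoint_table", "BehaviorFitter"]


@dataclass(frozen=True)
class SweepGrid:
    """Candidate values for each model parameter (axes must be nonempty)."""

    m_values: tuple = (2, 5, 10, 15, 20, 30, 40, 60)
    n_values: tuple = (0.0, 0.5, 1.0, 2.0, 4.0)
    pi_values: tuple = (0.001, 0.01, 0.1)
    tau_values: tuple = (0.25, 0.5, 0.75, 0.9)
    D: int = 2

    def __post_init__(self) -> None:
        for name in ("m_values", "n_values", "pi_values", "tau_values"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be nonempty")

    @property
    def size(self) -> int:
        return (len(self.m_values) * len(self.n_values)
                * len(self.pi_values) * len(self.tau_values))


def default_grid(D: int = 2) -> SweepGrid:
    """The default sweep grid (held-constant values pi=0.01, tau=0.5 included)."""
    return SweepGrid(D=D)


def sweep(
    grid: SweepGrid,
    sequences: list[PitchSequence],
    manifest: pd.DataFrame | None = None,
    prior: PriorHyperparams | None = None,
    return_decisions: bool = False,
):
    """Model performance at every grid cell on a fixed stimulus set.

    Returns a DataFrame with one row per (D, m, n, pi, tau) cell carrying
    hit/FA rates (overall and per direction) and d'.  With
    ``return_decisions=True`` also returns a dict mapping
    ``(m, n, pi, tau) -> boolean per-trial decision array`` (trial order as in
    ``sequences``), which downstream code can reuse without re-running the
    model.  Deterministic given the stimulus seeds.
    """
    if manifest is None:
        manifest = sequences_to_manifest(sequences)
    trial_ids = [s.trial_id for s in sequences]
    rows = []
    decisions: dict[tuple, np.ndarray] = {}
    for m, n, pi in itertools.product(grid.m_values, grid.n_values, grid.pi_values):
        params = ModelParams(m=m, n=n, pi=pi, tau=grid.tau_values[0], D=grid.D)
        final_cp = np.array([
            run_model(seq, params, prior=prior, keep_beliefs=False).change_prob[-1]
            for seq in sequences
        ])
        for tau in grid.tau_values:
            dec = final_cp >= tau
            resp = pd.DataFrame({"trial_id": trial_ids, "response": dec})
            perf = performance_by_condition(resp, manifest).overall
            rows.append(dict(
                D=grid.D, m=m, n=n, pi=pi, tau=tau,
                hit=perf.hit_rate, fa=perf.fa_rate, dprime=perf.d_prime,
                hit_incr=perf.hit_incr, hit_decr=perf.hit_decr,
            ))
            if return_decisions:
                decisions[(m, n, pi, tau)] = dec
    table = pd.DataFrame(rows)
    return (table, decisions) if return_decisions else table


@dataclass(frozen=True)
class SubjectFit:
    """Best-matching sweep cell for one subject."""

    params: ModelParams
    distance: float
    subject_vector: np.ndarray
    model_vector: np.ndarray
    row: pd.Series = field(repr=False, default=None)


_VECTOR_COLS = {
    "by_direction": ["hit_incr", "hit_decr", "fa"],
    "overall": ["hit", "fa"],
}


def fit_subject(
    subject_perf,
    sweep_table: pd.DataFrame,
    vector: str = "by_direction",
) -> SubjectFit:
    """Nearest sweep cell to a subject's performance (Euclidean distance).

    ``subject_perf`` is a :class:`~stochtone.behavior.PerformancePoint` or an
    array matching the chosen vector layout.  Ties are broken by smallest m,
    then smallest n (parsimony), recorded in the fit.
    """
    if len(sweep_table) == 0:
        raise ValueError("empty sweep table")
    cols = _VECTOR_COLS[vector]
    if isinstance(subject_perf, PerformancePoint):
        target = subject_perf.vector(vector)
    else:
        target = np.asarray(subject_perf, dtype=float)
        if target.shape != (len(cols),):
            raise ValueError(f"subject vector must have shape ({len(cols)},) for {vector!r}")
    model_vecs = sweep_table[cols].to_numpy(dtype=float)
    dist = np.sqrt(((model_vecs - target[None, :]) ** 2).sum(axis=1))
    order = np.lexsort((sweep_table["n"].to_numpy(), sweep_table["m"].to_numpy(), dist))
    best = order[0]
    row = sweep_table.iloc[best]
    params = ModelParams(m=int(row["m"]), n=float(row["n"]), pi=float(row["pi"]),
                         tau=float(row["tau"]), D=int(row["D"]))
    return SubjectFit(params=params, distance=float(dist[best]),
                      subject_vector=target, model_vector=model_vecs[best], row=row)


def changepoint_table(
    traces,
    ioi: float = 0.175,
    trial_ids=None,
) -> pd.DataFrame:
    """Per-trial model changepoints in tone index and seconds.

    The changepoint is the earliest tone at which the change probability meets
    the decision threshold; undetected trials get NA.  Seconds are the tone's
    onset time (index x inter-onset interval).
    """
    rows = []
    for i, tr in enumerate(traces):
        cp = tr.changepoint
        rows.append(dict(
            trial_id=trial_ids[i] if trial_ids is not None else i,
            changepoint_tone=cp,
            changepoint_seconds=None if cp is None else cp * ioi,
            decision=tr.decision,
        ))
    df = pd.DataFrame(rows)
    df["changepoint_tone"] = df["changepoint_tone"].astype("Int64")
    return df


class BehaviorFitter(BaseEstimator):
    """Fit model parameters to subjects by nearest performance in ROC space.

    Parameters
    ----------
    sweep_table : DataFrame
        Output of :func:`sweep` on the stimulus set the subjects heard.
    vector : {"by_direction", "overall"}
        Performance vector used for the Euclidean distance.
    """

    def __init__(self, sweep_table=None, vector="by_direction"):
        self.sweep_table = sweep_table
        self.vector = vector

    def fit(self, X, y=None):
        """``X``: (n_subjects, len(vector)) array or list of PerformancePoint."""
        if self.sweep_table is None or len(self.sweep_table) == 0:
            raise ValueError("a nonempty sweep_table is required")
        self.fits_ = [fit_subject(x, self.sweep_table, vector=self.vector) for x in X]
        self.best_params_ = [f.params for f in self.fits_]
        self.distances_ = np.array([f.distance for f in self.fits_])
        return self

    def predict(self, X):
        """Model performance vectors of the best-fit cells for new subjects."""
        return np.stack([
            fit_subject(x, self.sweep_table, vector=self.vector).model_vector
            for x in X
        ])
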