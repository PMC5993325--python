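"""Perceptual Bayesian changepoint model for stochastic tone sequences.

The model performs Bayesian online changepoint detection over a melody of
pitches: it maintains a posterior over the current *run-length* (number of
observations since the most recent changepoint) and, for every run-length
hypothesis, conjugate Normal-Inverse-Wishart (NIW) sufficient statistics of
the observations in that run.  Each hypothesis yields a Student-t predictive
for the next pitch; the belief-weighted mixture of these is the model's
predictive distribution, whose negative log density at the observed pitch is
the *surprisal*.  The probability that at least one change has occurred is
``1 - P(run length = t)``.

Two perceptual constraints modify the ideal observer:

* a working-memory capacity ``m``: hypotheses with run length ``r >= m`` all
  use the statistics of only the last ``m`` observations;
* observation noise ``n`` (scale-step units): ``n^2 * I_D`` is added to the
  predictive scale matrix, putting a lower bound on prediction uncertainty.

The order ``D`` selects the statistics collected: ``D = 1`` tracks marginal
mean and variance (the lower-order-statistics, LOS, model); ``D = 2``
additionally tracks the covariance between successive pitches via overlapping
pairs (the higher-order-statistics, HOS, model); ``D = 3`` extends to triples.
For ``D >= 2`` the scalar prediction is the conditional of the D-variate
Student-t predictive given the trailing ``D - 1`` observed pitches (the
context crosses a hypothesized changepoint only through this conditioning,
never through the sufficient statistics, keeping runs independent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

from .stimuli import PitchSequence, DEFAULT_CLIP_SD

__all__ = [
    "PriorHyperparams", "ModelParams", "SufficientStats", "StudentT",
    "ModelTrace", "DetectorState", "ChangeDetector",
    "init_state", "update", "surprisal", "change_probability",
    "mixture_predictive", "hypothesis_predictive", "suffstats_from_window",
    "decide", "run_model", "default_prior_for_steps",
]


# ---------------------------------------------------------------------------
# parameters and priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorHyperparams:
    """Normal-Inverse-Wishart prior over the D-variate (mean, covariance).

    ``mu0``: prior mean (D,); ``kappa0``: pseudo-count on the mean;
    ``nu0``: degrees of freedom (> D - 1); ``lambda0``: scatter matrix (D, D),
    symmetric positive-definite.
    """

    mu0: np.ndarray
    kappa0: float
    nu0: float
    lambda0: np.ndarray

    def __post_init__(self) -> None:
        mu0 = np.atleast_1d(np.asarray(self.mu0, dtype=float))
        lam = np.atleast_2d(np.asarray(self.lambda0, dtype=float))
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "lambda0", lam)
        D = mu0.shape[0]
        if lam.shape != (D, D):
            raise ValueError("lambda0 must be (D, D) matching mu0")
        if not np.allclose(lam, lam.T):
            raise ValueError("lambda0 must be symmetric")
        if np.any(np.linalg.eigvalsh(lam) <= 0):
            raise ValueError("lambda0 must be positive-definite")
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be > 0")
        if self.nu0 <= D - 1:
            raise ValueError("nu0 must exceed D - 1")

    @property
    def D(self) -> int:
        return self.mu0.shape[0]


def default_prior_for_steps(
    D: int,
    n_steps: int = 35,
    clip_sd: float = DEFAULT_CLIP_SD,
    kappa0: float = 1.0,
) -> PriorHyperparams:
    """Default prior for melodies on an ``n_steps``-step scale.

    The prior mean sits at the scale midpoint and the scatter is the identity
    scaled to the stimulus variance implied by the quantization mapping (one
    standard deviation spans ``(n_steps - 1) / (2 * clip_sd)`` steps), with
    ``nu0 = D + 2`` so the prior expected covariance equals that scatter.
    """
    loc = (n_steps - 1) / 2.0
    scale2 = ((n_steps - 1) / (2.0 * clip_sd)) ** 2
    return PriorHyperparams(
        mu0=np.full(D, loc),
        kappa0=kappa0,
        nu0=D + 2.0,
        lambda0=scale2 * np.eye(D),
    )


@dataclass(frozen=True)
class ModelParams:
    """The model's free parameters.

    ``m``: memory capacity in observations (``None`` = unbounded);
    ``n``: observation-noise SD in scale-step units; ``pi``: per-step
    change-prior probability; ``tau``: decision threshold on the final change
    probability; ``D``: statistic order (1 = LOS, 2 = HOS).
    """

    m: int | None = None
    n: float = 0.0
    pi: float = 0.01
    tau: float = 0.5
    D: int = 2
    prior: PriorHyperparams | None = None
    prune_threshold: float = 1e-12
    predictive: str = "student_t"

    def __post_init__(self) -> None:
        if self.predictive not in ("student_t", "plugin_gaussian"):
            raise ValueError("predictive must be 'student_t' or 'plugin_gaussian'")
        if self.m is not None and (int(self.m) != self.m or self.m < 1):
            raise ValueError("m must be a positive integer or None (unbounded)")
        if self.n < 0:
            raise ValueError("observation noise n must be >= 0")
        if not 0 <= self.pi < 1:
            raise ValueError("change-prior pi must be in [0, 1)")
        if not 0 < self.tau <= 1:
            raise ValueError("threshold tau must be in (0, 1]")
        if self.D not in (1, 2, 3):
            raise ValueError("statistic order D must be 1, 2, or 3")
        if self.prior is not None and self.prior.D != self.D:
            raise ValueError("prior dimensionality must equal D")

    def resolved_prior(self, n_steps: int | None = None) -> PriorHyperparams:
        if self.prior is not None:
            return self.prior
        return default_prior_for_steps(self.D, n_steps=n_steps or 35)


# ---------------------------------------------------------------------------
# Student-t predictive densities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudentT:
    """Univariate location-scale Student-t density."""

    df: float
    loc: float
    scale2: float

    def logpdf(self, x) -> np.ndarray | float:
        return _t_logpdf(np.asarray(x, dtype=float), self.df, self.loc, self.scale2)

    def pdf(self, x) -> np.ndarray | float:
        return np.exp(self.logpdf(x))

    @property
    def mean(self) -> float:
        return self.loc

    @property
    def var(self) -> float:
        if math.isinf(self.df):
            return self.scale2
        if self.df <= 2:
            return math.inf
        return self.scale2 * self.df / (self.df - 2.0)


def _t_logpdf(x, df, loc, scale2):
    """Student-t log density; ``df = inf`` falls back to the Gaussian limit."""
    df = np.asarray(df, dtype=float)
    z2 = (x - loc) ** 2 / scale2
    if np.all(np.isinf(df)):
        return -0.5 * (np.log(2.0 * np.pi * scale2) + z2)
    dff = np.where(np.isinf(df), 1.0, df)  # placeholder, overwritten below
    out = (
        gammaln((dff + 1.0) / 2.0) - gammaln(dff / 2.0)
        - 0.5 * np.log(dff * np.pi * scale2)
        - (dff + 1.0) / 2.0 * np.log1p(z2 / dff)
    )
    return np.where(np.isinf(df), -0.5 * (np.log(2.0 * np.pi * scale2) + z2), out)


# ---------------------------------------------------------------------------
# sufficient statistics and single-hypothesis predictive (reference path)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SufficientStats:
    """Per-hypothesis D-tuple statistics: mean, covariance (MLE), tuple count."""

    mean: np.ndarray
    cov: np.ndarray
    count: int

    @property
    def D(self) -> int:
        return np.atleast_1d(self.mean).shape[0]


def suffstats_from_window(window: np.ndarray, D: int) -> SufficientStats:
    """Statistics of the overlapping D-tuples within a window of observations."""
    w = np.asarray(window, dtype=float)
    q = max(0, w.size - D + 1)
    if q == 0:
        return SufficientStats(np.zeros(D), np.zeros((D, D)), 0)
    tuples = np.stack([w[j : j + q] for j in range(D)], axis=1)  # oldest coord first
    mean = tuples.mean(axis=0)
    dev = tuples - mean
    cov = dev.T @ dev / q
    return SufficientStats(mean, cov, q)


def hypothesis_predictive(
    stats: SufficientStats,
    prior: PriorHyperparams,
    n: float = 0.0,
    x_context: np.ndarray | None = None,
    predictive: str = "student_t",
) -> StudentT:
    """Posterior-predictive density for the next pitch under one hypothesis.

    Forms the NIW posterior from the D-tuple statistics, takes the D-variate
    Student-t posterior predictive, adds ``n^2 * I`` to its scale matrix, and
    conditions on the trailing ``D - 1`` observed values ``x_context`` (fewer
    are allowed near the sequence start: the missing coordinates are
    marginalized out).  For ``D = 1`` no conditioning occurs.
    """
    D = prior.D
    q = stats.count
    kn = prior.kappa0 + q
    nun = prior.nu0 + q
    if q > 0:
        mun = (prior.kappa0 * prior.mu0 + q * stats.mean) / kn
        dev = (stats.mean - prior.mu0).reshape(-1, 1)
        lamn = prior.lambda0 + q * stats.cov + (prior.kappa0 * q / kn) * (dev @ dev.T)
    else:
        mun = prior.mu0.copy()
        lamn = prior.lambda0.copy()
    if predictive == "plugin_gaussian":
        df0 = math.inf
        sigma = lamn / (nun - D - 1.0) + n**2 * np.eye(D)
    else:
        df0 = nun - D + 1.0
        sigma = lamn * (kn + 1.0) / (kn * df0) + n**2 * np.eye(D)

    context = np.atleast_1d(np.asarray(x_context, dtype=float)) if x_context is not None else np.empty(0)
    c_len = min(context.size, D - 1)
    context = context[context.size - c_len :]
    # marginalize down to the last (c_len + 1) coordinates, then condition
    sel = slice(D - 1 - c_len, D)
    mu_s = mun[sel]
    sig_s = sigma[sel, sel.start : sel.stop]
    if c_len == 0:
        return StudentT(df0, float(mu_s[-1]), float(sig_s[-1, -1]))
    s11 = sig_s[:c_len, :c_len]
    s12 = sig_s[:c_len, -1]
    s22 = float(sig_s[-1, -1])
    dev_c = context - mu_s[:c_len]
    sol = np.linalg.solve(s11, np.stack([s12, dev_c], axis=1))
    delta = float(dev_c @ sol[:, 1])
    loc = float(mu_s[-1] + s12 @ sol[:, 1])
    schur = s22 - float(s12 @ sol[:, 0])
    if predictive == "plugin_gaussian":
        return StudentT(math.inf, loc, schur)
    scale2 = (df0 + delta) / (df0 + c_len) * schur
    return StudentT(df0 + c_len, loc, float(scale2))


# ---------------------------------------------------------------------------
# vectorized predictive over all run-length hypotheses (fast path)
# ---------------------------------------------------------------------------

class _TupleSums:
    """Prefix sums of lagged moments, for O(1) windowed D-tuple statistics.

    Coordinate ``j`` of a tuple ending at observation ``i`` is ``x[i - (D-1-j)]``;
    prefix position ``p`` indexes tuples ending at ``i = p + D - 1``.
    """

    def __init__(self, x: np.ndarray, D: int):
        x = np.asarray(x, dtype=float)
        self.D = D
        T = x.size
        n_tuples = max(0, T - D + 1)
        self.first = np.zeros((D, n_tuples + 1))
        self.second = np.zeros((D, D, n_tuples + 1))
        if n_tuples > 0:
            coords = np.stack([x[j : j + n_tuples] for j in range(D)], axis=0)
            np.cumsum(coords, axis=1, out=self.first[:, 1:])
            prods = coords[:, None, :] * coords[None, :, :]
            np.cumsum(prods, axis=2, out=self.second[:, :, 1:])

    def window_stats(self, t: int, w: np.ndarray):
        """Mean vectors and scatter matrices over windows of the last ``w`` obs.

        Windows end at observation ``t - 1``.  Returns ``(q, mean, scatter)``
        with shapes (R,), (R, D), (R, D, D); hypotheses with fewer than D
        observations get ``q = 0`` and zero stats.
        """
        D = self.D
        q = np.maximum(0, w - D + 1)
        hi = t - D + 1  # one past the last tuple position
        lo = np.maximum(0, np.minimum(hi, t - w))
        hi = max(0, hi)
        s1 = self.first[:, hi] [:, None] - self.first[:, lo]          # (D, R)
        s2 = self.second[:, :, hi][:, :, None] - self.second[:, :, lo]  # (D, D, R)
        qs = np.where(q > 0, q, 1).astype(float)
        mean = (s1 / qs).T                                            # (R, D)
        scatter = np.moveaxis(s2, -1, 0) - qs[:, None, None] * mean[:, :, None] * mean[:, None, :]
        zero = q <= 0
        mean[zero] = 0.0
        scatter[zero] = 0.0
        return q, mean, scatter


def _batched_predictive(q, mean, scatter, prior: PriorHyperparams, n: float,
                        context: np.ndarray, predictive: str = "student_t"):
    """Conditional predictive parameters (df, loc, scale2) for all hypotheses.

    ``df = inf`` encodes the plug-in Gaussian variant (point posterior
    estimates instead of the full Student-t posterior predictive).
    """
    D = prior.D
    kn = prior.kappa0 + q
    nun = prior.nu0 + q
    mun = (prior.kappa0 * prior.mu0[None, :] + q[:, None] * mean) / kn[:, None]
    dev = mean - prior.mu0[None, :]
    lamn = (
        prior.lambda0[None, :, :]
        + scatter
        + (prior.kappa0 * q / kn)[:, None, None] * dev[:, :, None] * dev[:, None, :]
    )
    if predictive == "plugin_gaussian":
        # posterior-mean covariance estimate; Gaussian conditioning below
        df0 = np.full(q.shape, np.inf)
        sigma = lamn / (nun - D - 1.0)[:, None, None] + (n**2) * np.eye(D)[None, :, :]
    else:
        df0 = nun - D + 1.0
        sigma = lamn * ((kn + 1.0) / (kn * df0))[:, None, None] + (n**2) * np.eye(D)[None, :, :]

    c_len = min(context.size, D - 1)
    ctx = context[context.size - c_len :]
    sel = slice(D - 1 - c_len, D)
    mu_s = mun[:, sel]
    sig_s = sigma[:, sel, sel]
    if c_len == 0:
        return df0, mu_s[:, -1], sig_s[:, -1, -1]
    s11 = sig_s[:, :c_len, :c_len]
    s12 = sig_s[:, :c_len, -1]
    s22 = sig_s[:, -1, -1]
    dev_c = ctx[None, :] - mu_s[:, :c_len]
    rhs = np.stack([s12, dev_c], axis=2)             # (R, c, 2)
    sol = np.linalg.solve(s11, rhs)
    delta = np.einsum("rc,rc->r", dev_c, sol[:, :, 1])
    loc = mu_s[:, -1] + np.einsum("rc,rc->r", s12, sol[:, :, 1])
    schur = s22 - np.einsum("rc,rc->r", s12, sol[:, :, 0])
    if predictive == "plugin_gaussian":
        return df0, loc, schur
    df = df0 + c_len
    scale2 = (df0 + delta) / (df0 + c_len) * schur
    return df, loc, scale2


# ---------------------------------------------------------------------------
# detector state and trace
# ---------------------------------------------------------------------------

class DetectorState:
    """Mutable state of the sequential changepoint detector.

    Holds the observation history and the run-length belief; see module
    docstring for the update equations.
    """

    def __init__(self, params: ModelParams, prior: PriorHyperparams | None = None,
                 n_steps: int | None = None):
        self.params = params
        self.prior = prior or params.resolved_prior(n_steps)
        if self.prior.D != params.D:
            raise ValueError("prior dimensionality must equal params.D")
        self.x: list[float] = []
        self.log_weights = np.zeros(1)  # point mass at run length 0
        self._sums: _TupleSums | None = None
        self._sums_cover = 0

    # -- internal -----------------------------------------------------------

    @property
    def t(self) -> int:
        return len(self.x)

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    def _window_lengths(self) -> np.ndarray:
        r = np.arange(self.t + 1)
        m = self.params.m
        return r if m is None else np.minimum(r, m)

    def _seed_sums(self, full_x: np.ndarray) -> None:
        """Precompute prefix sums for a known full sequence (optimization)."""
        self._sums = _TupleSums(np.asarray(full_x, dtype=float), self.params.D)
        self._sums_cover = len(full_x)

    def _predictive_params(self):
        """(df, loc, scale2) arrays over run-length hypotheses 0..t."""
        xarr = np.asarray(self.x, dtype=float)
        if self._sums is None or self._sums_cover < xarr.size:
            self._seed_sums(xarr)
        q, mean, scatter = self._sums.window_stats(self.t, self._window_lengths())
        context = xarr[max(0, self.t - (self.params.D - 1)) : self.t]
        return _batched_predictive(q, mean, scatter, self.prior, self.params.n,
                                   context, predictive=self.params.predictive)

    def mixture_logpdf(self, x_next: float) -> float:
        df, loc, scale2 = self._predictive_params()
        logp = _t_logpdf(float(x_next), df, loc, scale2)
        return float(logsumexp(self.log_weights + logp))

    def predictive_moments(self) -> tuple[float, float]:
        """Mean and variance of the mixture predictive for the next pitch."""
        df, loc, scale2 = self._predictive_params()
        w = self.weights
        with np.errstate(invalid="ignore"):
            var = np.where(np.isinf(df), scale2, scale2 * df / (df - 2.0))
        mean = float(w @ loc)
        return mean, float(w @ (var + loc**2) - mean**2)

    def hypothesis_predictives(self) -> list[StudentT]:
        df, loc, scale2 = self._predictive_params()
        return [StudentT(float(d), float(l), float(s)) for d, l, s in zip(df, loc, scale2)]

    # -- update -------------------------------------------------------------

    def update(self, x_obs: float) -> float:
        """Incorporate one observation; returns the surprisal (nats)."""
        if not np.isfinite(x_obs):
            raise ValueError("observation must be finite")
        df, loc, scale2 = self._predictive_params()
        logp = _t_logpdf(float(x_obs), df, loc, scale2)
        joint = self.log_weights + logp
        lse = float(logsumexp(joint))
        pi = self.params.pi
        new_lw = np.empty(self.t + 2)
        with np.errstate(divide="ignore"):
            # normalized: run-length-0 mass is exactly pi; survivors share 1 - pi
            new_lw[0] = np.log(pi)
            new_lw[1:] = np.log1p(-pi) + joint - lse
        self.x.append(float(x_obs))
        self.log_weights = new_lw
        self._prune()
        return -lse

    def _prune(self) -> None:
        thr = self.params.prune_threshold
        m = self.params.m
        if thr <= 0 or m is None or self.t <= m + 1:
            return
        w = np.exp(self.log_weights)
        r = np.arange(w.size)
        kill = (w < thr) & (r > m) & (r < w.size - 1)
        if kill.any():
            w[kill] = 0.0
            w /= w.sum()
            with np.errstate(divide="ignore"):
                self.log_weights = np.log(w)

    def change_probability(self) -> float:
        if self.t < 1:
            raise ValueError("change probability is defined only after an observation")
        return float(1.0 - np.exp(self.log_weights[-1]))


@dataclass
class ModelTrace:
    """Per-time model outputs over one melody."""

    pred_mean: np.ndarray
    pred_var: np.ndarray
    surprisal: np.ndarray
    change_prob: np.ndarray
    beliefs: list[np.ndarray]
    decision: bool
    changepoint: int | None
    params: ModelParams = field(repr=False, default=None)

    def __len__(self) -> int:
        return self.surprisal.size


# ---------------------------------------------------------------------------
# functional interface
# ---------------------------------------------------------------------------

def init_state(params: ModelParams, prior: PriorHyperparams | None = None,
               n_steps: int | None = None) -> DetectorState:
    """Fresh detector state: belief is a point mass at run length 0."""
    return DetectorState(params, prior=prior, n_steps=n_steps)


def update(state: DetectorState, x_obs: float) -> DetectorState:
    """Advance the detector by one observation (mutates and returns state)."""
    state.update(x_obs)
    return state


def surprisal(state: DetectorState, x_obs: float) -> float:
    """Negative log mixture-predictive density of ``x_obs`` (nats), pre-update."""
    return -state.mixture_logpdf(x_obs)


def mixture_predictive(state: DetectorState, x_next: float) -> float:
    """Mixture predictive density at a candidate next value."""
    return math.exp(state.mixture_logpdf(x_next))


def change_probability(state: DetectorState) -> float:
    """Probability that at least one change has occurred: 1 - P(r_t = t)."""
    return state.change_probability()


def decide(trace, tau: float) -> tuple[bool, int | None]:
    """Change decision and model changepoint from a change-probability trace.

    ``trace`` is a :class:`ModelTrace` or a raw change-probability array.  The
    decision compares the *final* change probability to ``tau``; the
    changepoint is the earliest 0-based tone index where the trace meets
    ``tau`` (``None`` if it never does).  A trace may cross and dip back:
    a changepoint can exist while the decision is "no".
    """
    if isinstance(trace, ModelTrace):
        trace = trace.change_prob
    c = np.asarray(trace, dtype=float)
    if c.size == 0:
        raise ValueError("empty change-probability trace")
    hits = np.nonzero(c >= tau)[0]
    return bool(c[-1] >= tau), (int(hits[0]) if hits.size else None)


def run_model(seq, params: ModelParams, prior: PriorHyperparams | None = None,
              keep_beliefs: bool = True) -> ModelTrace:
    """Run the detector over a full melody and collect its outputs.

    ``seq`` may be a :class:`~stochtone.stimuli.PitchSequence` or a 1-D array
    of pitch values.  The model is causal: outputs at tone ``t`` depend only
    on tones ``0..t``.
    """
    if isinstance(seq, PitchSequence):
        x = seq.pitches.astype(float)
        n_steps = seq.n_steps
    else:
        x = np.asarray(seq, dtype=float)
        n_steps = None
    state = init_state(params, prior=prior, n_steps=n_steps)
    state._seed_sums(x)
    T = x.size
    pred_mean = np.empty(T)
    pred_var = np.empty(T)
    surp = np.empty(T)
    cprob = np.empty(T)
    beliefs: list[np.ndarray] = []
    for t in range(T):
        pred_mean[t], pred_var[t] = state.predictive_moments()
        surp[t] = state.update(x[t])
        cprob[t] = state.change_probability()
        if keep_beliefs:
            beliefs.append(state.weights)
    decision, changepoint = decide(cprob, params.tau)
    return ModelTrace(pred_mean, pred_var, surp, cprob, beliefs,
                      decision, changepoint, params)


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class ChangeDetector(BaseEstimator):
    """Bayesian run-length change detector over pitch sequences.

    scikit-learn-style wrapper around :func:`run_model`: ``X`` is a list of
    :class:`~stochtone.stimuli.PitchSequence` (or 1-D pitch arrays).

    Parameters
    ----------
    memory : int or None
        Working-memory capacity ``m`` in observations (None = unbounded).
    noise : float
        Observation-noise SD ``n`` in scale-step units.
    change_prior : float
        Per-step changepoint prior ``pi``.
    threshold : float
        Decision threshold ``tau`` on the final change probability.
    order : int
        Statistic order ``D``: 1 = LOS (mean/variance), 2 = HOS (+ lag-1
        covariance), 3 adds lag-2 structure.
    n_steps : int or None
        Scale size used to build the default prior when a sequence does not
        carry one (ignored when ``prior`` is given).
    prior : PriorHyperparams or None
        Explicit NIW prior; overrides ``n_steps``.
    """

    def __init__(self, memory=None, noise=0.0, change_prior=0.01, threshold=0.5,
                 order=2, n_steps=None, prior=None, prune_threshold=1e-12):
        self.memory = memory
        self.noise = noise
        self.change_prior = change_prior
        self.threshold = threshold
        self.order = order
        self.n_steps = n_steps
        self.prior = prior
        self.prune_threshold = prune_threshold

    def _params(self) -> ModelParams:
        return ModelParams(m=self.memory, n=self.noise, pi=self.change_prior,
                           tau=self.threshold, D=self.order, prior=self.prior,
                           prune_threshold=self.prune_threshold)

    def fit(self, X=None, y=None):
        """Validate parameters (the detector has no trainable state)."""
        self.params_ = self._params()
        return self

    def transform(self, X) -> list[ModelTrace]:
        """Full model traces, one per sequence."""
        if not hasattr(self, "params_"):
            self.fit()
        prior = self.prior
        if prior is None and self.n_steps is not None:
            prior = default_prior_for_steps(self.order, self.n_steps)
        return [run_model(seq, self.params_, prior=prior) for seq in X]

    def predict_proba(self, X) -> np.ndarray:
        """Final change probability per sequence."""
        return np.array([tr.change_prob[-1] for tr in self.transform(X)])

    def predict(self, X) -> np.ndarray:
        """Yes/no change decisions per sequence."""
        return self.predict_proba(X) >= self.threshold

    def changepoints(self, X) -> list[int | None]:
        """Earliest threshold-crossing tone index per sequence (None if never)."""
        return [tr.changepoint for tr in self.transform(X)]
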