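"""Run-length inference model: predictives, updates, outputs, decisions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs

from stochtone.model import (
    ChangeDetector,
    ModelParams,
    PriorHyperparams,
    change_probability,
    decide,
    default_prior_for_steps,
    hypothesis_predictive,
    init_state,
    mixture_predictive,
    run_model,
    suffstats_from_window,
    surprisal,
    update,
)
from stochtone.stimuli import compose_change_trial, generate_control_trial


# ---------------------------------------------------------------------------
# parameters and priors
# ---------------------------------------------------------------------------

class TestParams:
    @pytest.mark.parametrize("bad", [
        dict(m=0), dict(m=2.5), dict(n=-1), dict(pi=1.0), dict(pi=-0.1),
        dict(tau=0.0), dict(tau=1.5), dict(D=4), dict(predictive="map"),
    ])
    def test_invalid_params_raise(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorHyperparams(mu0=[0, 0], kappa0=1, nu0=3,
                             lambda0=[[1, 2], [2, 1]])  # not PD
        with pytest.raises(ValueError):
            PriorHyperparams(mu0=[0, 0], kappa0=1, nu0=0.5, lambda0=np.eye(2))
        with pytest.raises(ValueError):
            PriorHyperparams(mu0=[0], kappa0=0, nu0=3, lambda0=[[1]])

    def test_prior_dimension_must_match_order(self):
        with pytest.raises(ValueError):
            ModelParams(D=2, prior=default_prior_for_steps(1))


# ---------------------------------------------------------------------------
# initial state and hypothesis predictives
# ---------------------------------------------------------------------------

class TestInitState:
    def test_point_mass_at_run_length_zero(self):
        state = init_state(ModelParams(D=1))
        assert state.weights.shape == (1,)
        assert state.weights[0] == 1.0
        assert state.t == 0

    def test_initial_predictive_equals_prior_predictive(self):
        prior = default_prior_for_steps(1)
        state = init_state(ModelParams(D=1, prior=prior))
        got = state.hypothesis_predictives()[0]
        ref = hypothesis_predictive(suffstats_from_window([], 1), prior)
        assert got.df == pytest.approx(ref.df)
        assert got.loc == pytest.approx(prior.mu0[0])
        assert got.scale2 == pytest.approx(ref.scale2)

    def test_change_probability_undefined_before_data(self):
        state = init_state(ModelParams(D=1))
        with pytest.raises(ValueError):
            change_probability(state)


class TestHypothesisPredictive:
    def test_long_run_converges_to_generating_distribution(self, rng):
        """Mean -> 3, variance -> 1 on i.i.d. Normal(3,1) data at w=2000, n=0."""
        x = rng.normal(3.0, 1.0, size=2000)
        prior = PriorHyperparams(mu0=[0.0], kappa0=1.0, nu0=3.0, lambda0=[[1.0]])
        pred = hypothesis_predictive(suffstats_from_window(x, 1), prior, n=0.0)
        assert abs(pred.mean - 3.0) < 0.15
        assert abs(pred.var - 1.0) < 0.05

    def test_conditioning_shrinks_variance_on_correlated_data(self, rng):
        """On AR(1) data the lag-aware (D=2) conditional beats the marginal."""
        phi, T = 0.9, 1500
        x = np.empty(T)
        x[0] = 0.0
        for t in range(1, T):
            x[t] = phi * x[t - 1] + rng.normal()
        p1 = hypothesis_predictive(suffstats_from_window(x, 1),
                                   default_prior_for_steps(1))
        p2 = hypothesis_predictive(suffstats_from_window(x, 2),
                                   default_prior_for_steps(2), x_context=x[-1:])
        assert p2.var < p1.var
        # oracle: conditional variance of the generating AR(1) is 1
        assert abs(p2.var - 1.0) < 0.1

    @pytest.mark.parametrize("D", [1, 2, 3])
    @pytest.mark.parametrize("w", [0, 1, 3, 12])
    def test_noise_floor_on_predictive_variance(self, rng, D, w):
        x = rng.normal(17, 6, size=w)
        for n in (0.5, 2.0, 4.0):
            pred = hypothesis_predictive(suffstats_from_window(x, D),
                                         default_prior_for_steps(D), n=n,
                                         x_context=x[max(0, w - D + 1):])
            assert pred.var >= n**2

    def test_empty_run_ignores_data_scale(self, rng):
        """Run length 0 predictive equals the prior predictive."""
        prior = default_prior_for_steps(1)
        a = hypothesis_predictive(suffstats_from_window([], 1), prior)
        b = hypothesis_predictive(suffstats_from_window(rng.normal(size=0), 1), prior)
        assert a == b

    def test_plugin_gaussian_predictive(self, rng):
        x = rng.normal(17, 6, size=50)
        pred = hypothesis_predictive(suffstats_from_window(x, 1),
                                     default_prior_for_steps(1),
                                     predictive="plugin_gaussian")
        assert np.isinf(pred.df)
        assert pred.var == pred.scale2


# ---------------------------------------------------------------------------
# mixture predictive
# ---------------------------------------------------------------------------

class TestMixture:
    def _state_after(self, xs, **kw):
        kw.setdefault("D", 2)
        state = init_state(ModelParams(**kw))
        for x in xs:
            update(state, x)
        return state

    def test_integrates_to_one_by_quadrature(self, rng):
        state = self._state_after(rng.normal(17, 6, size=8), pi=0.05)
        grid = np.linspace(-200, 230, 20001)
        dens = np.array([mixture_predictive(state, g) for g in grid])
        integral = np.trapezoid(dens, grid)
        assert abs(integral - 1.0) < 1e-3
        assert np.all(dens >= 0)

    def test_single_hypothesis_degenerates_to_component(self, rng):
        state = self._state_after(rng.normal(17, 6, size=4), pi=0.0)
        comp = state.hypothesis_predictives()[-1]
        for x in (3.0, 17.0, 30.0):
            assert mixture_predictive(state, x) == pytest.approx(comp.pdf(x))

    def test_mixture_bounded_by_max_component(self, rng):
        state = self._state_after(rng.normal(17, 6, size=6), pi=0.1)
        comps = state.hypothesis_predictives()
        for x in np.linspace(0, 34, 11):
            assert mixture_predictive(state, x) <= max(c.pdf(x) for c in comps) + 1e-12


# ---------------------------------------------------------------------------
# belief updates
# ---------------------------------------------------------------------------

class TestUpdate:
    def test_zero_hazard_keeps_point_mass(self, rng):
        state = init_state(ModelParams(D=1, pi=0.0))
        for t, x in enumerate(rng.normal(17, 6, size=20), start=1):
            update(state, x)
            w = state.weights
            assert w[-1] == pytest.approx(1.0)
            assert change_probability(state) == pytest.approx(0.0)

    def test_first_update_change_mass_equals_hazard(self, rng):
        """Hand calculation: after one observation P(r=0) = pi exactly."""
        for pi in (0.01, 0.1, 0.3):
            state = init_state(ModelParams(D=2, pi=pi))
            update(state, 12.0)
            assert change_probability(state) == pytest.approx(pi, abs=1e-12)

    def test_weights_normalized_after_every_update(self, rng):
        state = init_state(ModelParams(D=2, pi=0.05, n=0.5, m=8))
        for x in rng.normal(17, 6, size=300):
            update(state, x)
            assert abs(state.weights.sum() - 1.0) < 1e-9

    def test_change_probability_complement_identity(self, rng):
        state = init_state(ModelParams(D=1, pi=0.02))
        for x in rng.normal(17, 6, size=30):
            update(state, x)
            w = state.weights
            assert change_probability(state) == pytest.approx(w[:-1].sum(), abs=1e-12)

    def test_non_finite_observation_raises(self):
        state = init_state(ModelParams(D=1))
        with pytest.raises(ValueError):
            update(state, np.nan)

    def test_surprisal_matches_mixture_density(self, rng):
        state = init_state(ModelParams(D=2, pi=0.05))
        for x in rng.normal(17, 6, size=10):
            s_pre = surprisal(state, x)
            assert s_pre == pytest.approx(-np.log(mixture_predictive(state, x)))
            s_upd = state.update(x)
            assert s_upd == pytest.approx(s_pre)

    def test_surprisal_increases_with_distance_from_mean(self, rng):
        for _ in range(20):
            state = init_state(ModelParams(D=1, pi=0.05))
            for x in rng.normal(17, 6, size=int(rng.integers(2, 15))):
                update(state, x)
            mean, var = state.predictive_moments()
            sd = np.sqrt(var)
            s0 = surprisal(state, mean)
            assert s0 < surprisal(state, mean + 3 * sd)
            assert s0 < surprisal(state, mean - 3 * sd)


@given(pi=hs.floats(0.0, 0.4), seed=hs.integers(0, 10_000))
@settings(deadline=None, max_examples=30)
def test_weights_sum_to_one_property(pi, seed):
    rng = np.random.default_rng(seed)
    state = init_state(ModelParams(D=2, pi=pi, m=5))
    for x in rng.normal(17, 6, size=12):
        update(state, x)
        assert abs(state.weights.sum() - 1.0) < 1e-9
        assert np.all(state.weights >= 0)


# ---------------------------------------------------------------------------
# decisions
# ---------------------------------------------------------------------------

class TestDecide:
    def test_printed_rule_examples(self):
        assert decide(np.zeros(5), 0.5) == (False, None)
        yes, cp = decide([0.1, 0.6, 0.4, 0.7], 0.5)
        assert yes and cp == 1
        # crossing without final exceedance: changepoint exists, decision no
        yes, cp = decide([0.1, 0.6, 0.4, 0.3], 0.5)
        assert not yes and cp == 1

    def test_impossible_threshold_never_detects(self):
        assert decide([0.2, 0.9, 1.0], 1.0 + 1e-9) == (False, None)

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            decide([], 0.5)


# ---------------------------------------------------------------------------
# full-melody runs
# ---------------------------------------------------------------------------

class TestRunModel:
    def test_causal_prefix_property(self, rng):
        x = rng.normal(17, 6, size=25)
        p = ModelParams(D=2, m=8, n=0.5, pi=0.02)
        full = run_model(x, p)
        part = run_model(x[:10], p)
        assert np.allclose(full.surprisal[:10], part.surprisal)
        assert np.allclose(full.change_prob[:10], part.change_prob)

    def test_inactive_memory_cap_equals_unbounded(self, rng):
        x = rng.normal(17, 6, size=20)
        a = run_model(x, ModelParams(D=2, m=None, pi=0.02))
        b = run_model(x, ModelParams(D=2, m=60, pi=0.02))
        assert np.allclose(a.change_prob, b.change_prob)
        assert np.allclose(a.surprisal, b.surprisal)

    def test_hypotheses_beyond_memory_share_predictives(self, rng):
        p = ModelParams(D=1, m=4, pi=0.05)
        state = init_state(p)
        for x in rng.normal(17, 6, size=15):
            update(state, x)
        preds = state.hypothesis_predictives()
        tail = preds[4:]
        for pred in tail[1:]:
            assert pred == tail[0]

    def test_los_hos_agree_without_covariance(self):
        """With zero lag-1 covariance the HOS predictive mean reduces to LOS:
        the fitted covariance (hence the conditional slope) vanishes as the
        run grows, up to O(1/sqrt(w)) sampling error."""
        diffs = []
        for s in range(20):
            r = np.random.default_rng(s)
            x = r.normal(17, 6, size=2000)
            p1 = hypothesis_predictive(suffstats_from_window(x, 1),
                                       default_prior_for_steps(1))
            p2 = hypothesis_predictive(suffstats_from_window(x, 2),
                                       default_prior_for_steps(2),
                                       x_context=x[-1:])
            diffs.append(abs(p1.mean - p2.mean))
        assert np.mean(diffs) < 0.2

    def test_change_trials_raise_change_probability(self):
        """HOS final change probability: change vs matched no-change trials."""
        deltas = []
        p = ModelParams(D=2, m=30, n=0.0, pi=0.01)
        for s in range(100):
            chg = compose_change_trial(2.0, 0.0, 60, seed=s)
            ctl = generate_control_trial(2.0, 60, seed=10_000 + s)
            deltas.append(run_model(chg, p).change_prob[-1]
                          - run_model(ctl, p).change_prob[-1])
        assert np.mean(deltas) > 0

    def test_trace_fields_complete(self, exp1_small):
        seqs, _ = exp1_small
        tr = run_model(seqs[0], ModelParams(D=2, m=10))
        T = len(seqs[0])
        assert len(tr) == T
        for arr in (tr.pred_mean, tr.pred_var, tr.surprisal, tr.change_prob):
            assert arr.shape == (T,) and np.all(np.isfinite(arr))
        assert len(tr.beliefs) == T
        assert tr.beliefs[-1].shape == (T + 1,)

    def test_noise_floor_holds_at_every_step(self, rng):
        n = 2.0
        state = init_state(ModelParams(D=2, m=6, n=n, pi=0.05))
        for x in rng.normal(17, 6, size=30):
            for pred in state.hypothesis_predictives():
                assert pred.var >= n**2
            update(state, x)


# ---------------------------------------------------------------------------
# sklearn estimator facade
# ---------------------------------------------------------------------------

class TestChangeDetector:
    def test_get_set_params_roundtrip(self):
        det = ChangeDetector(memory=10, noise=0.5, order=1)
        params = det.get_params()
        assert params["memory"] == 10
        det2 = ChangeDetector().set_params(**params)
        assert det2.memory == 10 and det2.order == 1

    def test_predict_matches_run_model(self, exp1_small):
        seqs, _ = exp1_small
        sub = seqs[:6]
        det = ChangeDetector(memory=10, order=2, threshold=0.5).fit()
        proba = det.predict_proba(sub)
        dec = det.predict(sub)
        ref = [run_model(s, ModelParams(m=10, D=2)).change_prob[-1] for s in sub]
        assert np.allclose(proba, ref)
        assert np.array_equal(dec, np.asarray(ref) >= 0.5)

    def test_changepoints_are_first_crossings(self, exp1_small):
        seqs, _ = exp1_small
        det = ChangeDetector(memory=10, order=2)
        cps = det.changepoints(seqs[:4])
        for cp, tr in zip(cps, det.transform(seqs[:4])):
            hits = np.nonzero(tr.change_prob >= 0.5)[0]
            assert cp == (int(hits[0]) if hits.size else None)
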