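# stochtone

Bayesian change detection in stochastic tone sequences.

`stochtone` is a toolbox for studying how a listener could detect changes in
the *statistics* of a melody that is itself random. It implements a
perceptual Bayesian online changepoint model over tone pitches, the
stochastic melody generators used to probe it (1/f^β random-fractal melodies
and first-order Markov melodies), signal-detection analysis of yes/no change
responses, sweep-based fitting of model parameters to individual behavior,
and model-guided EEG statistics (surprisal regression ERPs and
changepoint-locked phase-locking). Everything is exercisable end to end on
synthetic data; no human data is required.

## The model

The input is a pitch sequence x₁,…,x_T (scale-step units). Observations are
assumed Gaussian with unknown parameters that change at unknown changepoints;
observations after a change are independent of those before it. The model
maintains a posterior over the current *run length* r_t (tones since the last
change) and, per hypothesis, conjugate Normal–Inverse-Wishart statistics of
the run, producing a Student-t predictive for the next tone. Predictions are
combined across hypotheses:

    P(x_{t+1} | x_{1:t}) = Σ_r  P(x_{t+1} | r_t = r, x_{t-r+1:t}) · P(r_t = r | x_{1:t})

With each tone the beliefs are updated by the predictive likelihoods, and a
new run-length-0 hypothesis enters with the change-prior π. The model emits:

- **surprisal** S_t = −log P(x_t | x_{1:t−1}) (nats),
- **change probability** P(Change | x_{1:t}) = 1 − P(r_t = t | x_{1:t}),
- a **change decision** (final change probability ≥ τ) and a **model
  changepoint** (earliest t where the change probability reaches τ).

Two perceptual constraints make the ideal observer human-like: a working
memory capacity *m* (hypotheses with r ≥ m share statistics of only the last
m tones) and observation noise *n* (n²·I added to the predictive scale,
flooring prediction uncertainty). The statistic order D selects what is
tracked: D = 1 ("LOS") marginal mean and variance; D = 2 ("HOS") additionally
the covariance between successive tones, via overlapping pairs, with the
next-tone prediction obtained by conditioning on the previous tone.

## Worked example

```python
import stochtone as st
from stochtone.model import ModelParams, run_model

# an entropy-increasing change trial: 1/f^2 fractal -> white noise at tone 30
seq = st.compose_change_trial(2.0, 0.0, 60, seed=42)

hos = run_model(seq, ModelParams(m=30, n=0.0, pi=0.01, tau=0.5, D=2))
los = run_model(seq, ModelParams(m=30, n=0.0, pi=0.01, tau=0.5, D=1))
print(hos.decision, hos.changepoint, round(hos.change_prob[-1], 3))
print(los.decision, los.changepoint, round(los.change_prob[-1], 3))
```

prints

```
True 36 0.833
True 13 0.998
```

The HOS model flags the change at tone 36 — six tones after the true
midpoint, reflecting the evidence a statistical change needs to accumulate —
and ends the trial with change probability 0.833. The LOS model crosses
threshold already at tone 13: tracking only marginal statistics, it mistakes
the slow wander of the low-entropy first half for repeated mean changes, a
false alarm mechanism that caps its achievable sensitivity. Mean HOS
surprisal rises from 2.92 nats in the first half to 3.63 in the second,
the per-tone signature that the learned pair statistics stopped fitting.

The same objects drive the rest of the toolbox: `ChangeDetector` wraps the
model as a scikit-learn estimator, `fitting.sweep` tabulates hit/FA/d′ over
a {m, n, π, τ} grid, `fitting.fit_subject` picks the grid cell nearest a
subject's performance vector, and `eeg.rerp_fit` / `eeg.delta_plv_at_changepoints`
anchor single-trial EEG statistics to per-tone surprisal and per-trial model
changepoints. `stochtone --help` lists the command-line entry points.

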