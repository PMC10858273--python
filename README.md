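# triadic-ug

Simulation and Bayesian analysis of repeated dyadic/triadic ultimatum games
with partner choice.

## The problem

In a triadic ultimatum game, two proposers compete for one responder: each can
send 1–8 grapes out of 8, the responder accepts exactly one offer, and the
accepted proposer keeps the remainder.  When proposers must compete to be
chosen, generosity can escalate — *competitive altruism*.  A dyadic control
(one proposer at a time) separates competition effects from simple experience.
Triads play 16 counterbalanced sessions of 8 trials; triadic sessions split
into blocks of *simultaneous* trials (neither proposer sees the other's offer)
and *consecutive* trials (the second proposer sees the first offer before
offering — and can try to **outbid** it).

This package provides, for that design:

- a validated trial-level data model with CSV (de)serialization and a
  dialect adapter for external deposits (`triadic_ug.data_model`);
- the counterbalanced 16-session schedule generator and a constraint
  verifier (`triadic_ug.design`);
- an agent-based simulator: proposer strategies (minimal,
  reluctantly-increasing, threshold outbidder, …) and a reward-maximizing
  responder with ratio-dependent discrimination error (`triadic_ug.agents`);
- descriptive statistics (`triadic_ug.descriptives`);
- the hierarchical Bayesian model suite (`triadic_ug.models`, backed by
  `triadic_ug.bayes`);
- a weighted-resampling independence baseline for outbidding
  (`triadic_ug.baseline_outbid`);
- a simulation-based power analysis (`triadic_ug.power`);
- a CLI (`triadic-ug simulate|descriptives|fit|baseline|power|report`) and
  numbered analysis drivers under `analysis/`.

## The models

**Total proportional offer.**  For proposer *p* of triad *t* in session *s*,
the response is y = (grapes offered over the session) / (8 × opportunity
trials).  Then

    y ~ Beta(μφ, (1−μ)φ)
    logit(μ) = β0_c + β1_c·s̃ + u_t,       u_t ~ Normal(0, σ_μ)
    log(φ)   = γ0_c + v_t,                 v_t ~ Normal(0, σ_φ)

with condition-specific intercepts, session slopes and precisions
(c ∈ {dyadic, triadic}) and triad-level deviations on both the mean and the
precision.  A second fit restricted to the first four trials of each session
adds a contrast x ∈ {0, −0.5, +0.5} (dyadic / simultaneous / consecutive)
to logit(μ).

**Escalation models.**  Bernoulli GLMMs with proposer random intercepts:
last-offer-of-session > first-offer (condition × session), offer > own
previous offer (previous outcome × session), and offer ≥ previously accepted
offer (own-vs-other previous winner × session).

**Outbidding.**  For consecutive trials, P(second offer > first offer) with a
session effect; and a stratified model where the first-offer category
K ∈ {0..8} enters as a **monotonic ordinal effect**

    logit(p) = α0 + α_prev·a + (α_s + α_{prev×s}·a)·s̃ − b·Σ_{k≤K} ζ_k,
    b ≥ 0,  ζ ~ Dirichlet(1,…,1),

so the predicted outbid probability is non-increasing in the first offer for
every posterior draw, with freely estimated per-step drops.  Predictions are
compared against chance (0.5) and against a resampling **baseline**
B_K = Σ_{j>K} p_j, where p is a weighted empirical distribution of observed
first offers with exponential decay over trial and session indices.

Sampling uses an affine-invariant ensemble MCMC (emcee, differential-evolution
moves) with split-R̂ / ESS diagnostics via arviz; intervals are shortest-window
HPD intervals.

## Worked example

```
python analysis/01_simulate.py
python analysis/02_descriptives.py
```

prints, for the default strategy zoo (reluctantly-increasing proposers, one of
which outbids first offers of ≤ 3 grapes, and a noisy maximizer responder):

```
design generator: all counterbalance constraints verified
simulated 896 trials across 7 triads -> results/trials.csv
mean first offer (dyadic / triadic): 1.00 / 1.12
highest-offer acceptance rate (triadic): 0.967
mean offer ratio on errors: 0.757
P(choose right | first right): 0.259
P(choose left | first left): 0.366
trials: 896 total, 448 dyadic, 224 simultaneous, 224 consecutive
```

Every session opens at the strategy's floor offer (mean first offers near 1);
the responder takes the larger of two offers 97% of the time, and the errors
it does make happen when the two offers are similar (mean ratio 0.76).
Scripts `03`–`06` fit the Beta offer models, the escalation models, the
outbidding models with their baseline, and the power analysis, writing JSON
and CSV tables under `results/`.

## Data

The package defines its own canonical CSV schema (see
`triadic_ug.data_model.COLUMNS`).  External trial tables with different
column names or category labels can be loaded through the `dialect` /
`value_maps` arguments of `load_trials`, configured in YAML for the CLI.
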