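# Methods

This note documents the modeling and simulation choices behind `triadic_ug`:
what each component assumes, which knobs matter, and what the synthetic-data
tests do and do not establish.

## Experimental design

A triad is one responder plus two proposers playing 16 sessions of 8 trials.
`design.generate_design` builds the schedule deterministically from two
arguments (starting block type, first leading proposer).  Only the aggregate
counterbalance counts are binding constraints — 8 dyadic and 8 triadic
sessions; within triadic sessions two contiguous 4-trial blocks with
simultaneous-first in half the sessions; each proposer first on 2 of 4
consecutive trials per session and leading the block's first trial in 4
sessions; dyadic participation alternating every two trials with each
proposer opening half the sessions; sides swapping every two sessions.  The
inter-session orderings that realize those counts (strict block alternation,
the X-Y-Y-X within-block leader pattern) are this package's choice; any
ordering satisfying `verify_design` is equivalent for the models, which never
condition on order beyond the session index.

Sessions are indexed 1..16 chronologically across both block types, and that
single index is the session covariate everywhere.

## Data model

Offers are integers 0..8; 0 is reserved for "no offer within the time
window" and such trials are kept in the table (the responder may then have
accepted nothing) but excluded from every model response.  Dyadic trials have
exactly one offer opportunity; an accepted side must carry an offer ≥ 1;
`first_side` exists only on consecutive trials.  Lagged context
(`proposer_views`) never crosses a session boundary, and the lag skips trials
on which the proposer sent nothing: the "previous offer" is the proposer's
most recent *sent* offer of the same session.

The canonical CSV schema is defined here; external deposits are adapted via a
column-name dialect and category value maps rather than guessed at.

## Agents

The simulator is the package's synthetic-data generator and the definition of
its study conditions.

- *Reluctantly increasing proposer* (default): first offer 1; after a
  rejection the offer steps up by 1 (capped at 8); after an acceptance it is
  repeated, or with probability 0.25 creeps down by 1 (floored at 1).  The
  0.25 default keeps accepted offers sticky but not frozen, so within-session
  trajectories show both escalation and relaxation.
- *Threshold outbidder*: in the consecutive-second position with a visible
  first offer f, offers f+1 whenever the share kept, 8−(f+1), is at least 4
  grapes (i.e. outbids exactly f ≤ 3), else falls back to a configured
  strategy.  The share threshold of 4 encodes "outbid only while ending up
  with at least as much as the responder".
- *Responder*: accepts a lone valid offer; with two unequal offers picks the
  larger with probability 1−ε(r), where r = min/max and
  ε(r) = 0.5·exp(−(1−r)/w).  The exponential-in-(1−r) form is this package's
  choice; only ratio-dependence of discrimination error is externally
  motivated.  The default w = 0.15 concentrates errors at r ≥ 0.5 (e.g.
  ε ≈ 0.22 for 7 vs 8, ε ≈ 0.02 for 4 vs 8), so the simulated responder
  accepts the larger offer in the mid-90% range of trials with error ratios
  around 0.7 — qualitatively matching a near-maximizing responder whose
  mistakes cluster among similar offers.  Equal offers are broken by a side
  bias (default 0.5).
- Proposer state resets between sessions (configurable), consistent with the
  models treating each session's first trial as predecessor-free.  Timeouts
  (offer 0) have probability 0 by default.

What the simulator does *not* emulate: learning beyond the reluctant rule,
real-time response latencies, attention or visibility constraints, and any
individual heterogeneity beyond the strategy assignment.  Tests passing on
simulated data therefore certify the pipeline (design → behavior → table →
model → summaries), not claims about real chimpanzee behavior.

## Response definitions

- Total proportional offer: per proposer-session, grapes offered divided by
  8 × opportunity trials.  Per-proposer denominators are the default (64 for
  a full triadic session, 32 dyadic, halved for first-half fits); a
  session-level denominator (64 throughout) is available behind a switch, as
  reported per-trial offer averages imply the per-proposer convention.
- "Outbid" is strictly greater; "match the winner" is greater-or-equal.
- Equal-offer triadic trials are excluded from the highest-offer acceptance
  denominator ("highest" is undefined on ties).
- The chance reference for probabilities is 0.5.

## Inference

The sampling backend is emcee's affine-invariant ensemble sampler with a
differential-evolution move mixture (80% DE, 20% snooker), which mixes far
better than the default stretch move on these correlated hierarchical
posteriors.  Models expose a vectorized log-density over walker positions.
Defaults: walkers = max(2·ndim+2, 32); warmup 1000 ensemble steps; retained
states target chains × draws = 4000 with at least 250 post-warmup steps.
Post-warmup walker trajectories are treated as pseudo-chains for split-R̂ and
bulk-ESS (arviz); crossing R̂ > 1.01 or ESS < 400 emits a `ConvergenceWarning`
rather than failing, since reduced-precision fits inside power loops are
legitimate.

Parametrization and priors (all logged in `FitResult.priors`):

- fixed effects: Normal(0, 2.5) on logit/log scales;
- random-effect scales: half-Normal(1), sampled as log σ with the Jacobian;
  random effects non-centered (u = σ·z, z ~ Normal(0,1));
- monotonic magnitude b: half-Normal(2), sampled as log b;
- simplex ζ: Dirichlet(1,…,1) via the stick-breaking transform with its
  Jacobian.
- Beta responses are compressed from [0,1] to (0,1) by y ← (y(N−1)+0.5)/N
  (N = number of rows), since observed proportions can touch the boundary.
- The session covariate is standardized (mean 0, SD 1) within the fitted
  data; derived summaries are computed on the observed session labels, which
  makes them invariant to shifting labels by a constant.
- Posterior predictive condition summaries for the Beta models integrate over
  a fresh triad (new random deviations) at the mid-study session.
- Marginal probabilities from Bernoulli models integrate the inverse-logit
  over the random-intercept distribution by 31-point Gauss–Hermite
  quadrature, then average over observed sessions.

HPD intervals are shortest contiguous windows over sorted draws containing
⌈mass·n⌉ draws, checked against exhaustive window search.  Directional
probabilities are strict draw fractions.

Random-effect structure: proposer (or triad) intercepts everywhere; the
stratified outbidding model additionally gets (second proposer × responder)
pair intercepts by default, reflecting that outbidding varies most across
pairs.  Parameter-recovery tests for that model fit with pair effects off,
matching their generative process, because in a single-responder triad the
pair index is perfectly confounded with the proposer index.

## Baseline outbidding null

The null asks how often a second offer drawn *independently* of the first
would exceed it, with both drawn from an estimated offer-preference
distribution p over 0..8.  Preferences are estimated from observed *first*
offers only (second offers may be strategic), weighted by
exp(−λ_trial(trial−1))·exp(−λ_session(session−1)) so that early, less
competition-contaminated trials dominate; λ_trial = λ_session = 0.2 by
default and both are exposed in configuration and output.  The closed form
B_k = Σ_{j>k} p_j is the production path; Monte-Carlo simulation of
consecutive sessions is retained as a fidelity check with per-category MC
standard errors, and agrees with the closed form to < 0.005 at 10⁶ pairs.

## Power analysis

A scenario fixes the design size, per-condition strategy configurations, and
the detection rule; each replicate simulates the full experiment, fits the
total-offer model at reduced sampler settings (2 chains × 500 draws), and
detects when the 95% HPD of the predictive dyadic−triadic difference excludes
zero.  Power is the detected fraction with an exact binomial interval;
replicate-level failures are logged, not fatal.  Because the detection rule
uses the *predictive* difference (individual-level Beta noise included), it
is conservative: only contrasts large relative to within-condition spread are
detected.

## Problem sizes

Test-time fits use 4 chains × 400 draws after 800 warmup steps;
parameter-recovery checks run 50 replicates per model at the study scale of
7 triads × 16 sessions; the baseline fidelity check uses 10⁶ simulated
pairs; the analysis drivers run 10 power replicates per scenario.  These
sizes were chosen so the full suite runs on a single desk-scale core while
keeping Monte-Carlo error well below the decision thresholds they feed.

## Known limitations

- The strategy zoo's defaults are plausible stand-ins, not reconstructions of
  any specific published power-analysis configuration.
- The weighting function and simulation size of the original outbidding
  baseline are not reproduced exactly; only the structure (independence null
  over a decay-weighted first-offer preference) is.
- Ensemble MCMC diagnostics treat walkers as pseudo-chains; walkers are not
  independent, so R̂ here is a heuristic rather than a guarantee.
- Bayesian interval coverage for fixed-truth parameters is close to, but not
  exactly, the nominal level (prior shrinkage); recovery tests therefore
  check pooled coverage against a 90% floor rather than 95% point equality.
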