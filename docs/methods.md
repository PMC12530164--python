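# Methods

## Model

Each trial of the change-detection task is a two-choice decision modeled as a
one-dimensional Wiener diffusion with drift. Evidence starts at `α·β` and
accumulates with mean rate `δ` and unit diffusion coefficient until it is
absorbed at 0 (*respond Same*) or `α` (*respond Different*); the response
time is the first-passage time plus a nondecision component `τ` for encoding
and motor execution. Fixing the diffusion coefficient at 1, with time in
seconds, is the standard identifiability convention — only three of
(drift, boundary, diffusion) scales are free.

The joint density of (choice, RT) is evaluated exactly from the two classical
series representations of the first-passage density on normalized time
`u = (t − τ)/α²`: the small-time expansion (sum over mirrored start points)
and the large-time expansion (sine series). Per evaluation we compute the
number of terms each representation needs for an absolute truncation error of
1e-7 and use the cheaper one. The upper-boundary density is obtained from the
lower-boundary form by the reflection `(δ, β) → (−δ, 1−β)`. Times at or
before `τ` return zero density rather than raising: the likelihood is defined
for every observed RT, and data cleaning is owned by the preprocessing layer.
The absorbing probability has the closed form
`P(upper) = (1 − e^{−2δαβ}) / (1 − e^{−2δα})` (the start fraction `β` when
`δ = 0`), implemented with `expm1` for stability.

Trial sampling is by inverse CDF: the boundary is drawn from the closed-form
absorbing probability and the conditional first-passage time is inverted on a
dense trapezoid grid of the exact density (8192 points, extent doubled until
the residual tail mass is below 1e-9). A Euler–Maruyama path simulator exists
only inside the test suite as an independent oracle (with the
Broadie–Glasserman boundary-shift continuity correction, since discretized
paths overshoot boundaries); it is never the production sampler.

## Hierarchy and coding

Person × condition parameter vectors are sampled on the scales used for all
inference and reporting: drift natural, initial bias on the logit scale,
boundary separation on the log scale, nondecision time in seconds. For each
condition `c` and parameter `k`,

    theta[i, c, k] ~ Normal(mu[c, k], sigma[c, k]),

with no constraints across the 16 cells. Response coding is stimulus coding:
the upper boundary is the *different* response, and the condition-level drift
magnitude enters each trial's likelihood positively on *different* trials and
negated on *same* trials. This is what makes a condition-level start-point
bias toward *different* meaningful; under accuracy coding the bias parameter
would conflate stimulus types. Accuracy coding is not offered.

Priors (all configurable in `ModelSpec`): group means Normal(0, 3²) for
drift, Normal(0, 1.5²) for logit bias and log boundary, Normal(0.3, 0.3²)
truncated at 0 for τ (seconds); group SDs half-Normal(1). These are weakly
informative on each sampling scale. As a numerical guard (not a modeling
choice), each person-condition τ is bounded above by that cell's minimum
retained RT, where the likelihood is identically zero anyway.

## Sampler

No probabilistic-programming backend is used; the model has its own MCMC
scheme tailored to its conditional structure:

1. **Person-condition cells** — componentwise random-walk Metropolis on each
   4-vector, one pass per sweep, against the cell's trial likelihood (numba
   kernel) and its conditional normal prior. Proposal scales adapt per cell
   and component toward 0.44 acceptance during warmup only.
2. **Condition means** — conjugate normal Gibbs updates (with rejection for
   the τ truncation).
3. **Condition SDs** — random-walk Metropolis on log σ with the half-normal
   prior and log-scale Jacobian.
4. **Interweaved non-centered moves** — per (condition, parameter), a joint
   translation of the group mean together with all its person values, and a
   joint rescale of person deviations together with the group SD (the prior
   term cancels against the Jacobian of the deterministic rescale). These are
   ancillarity–sufficiency interweaving moves; without them the centered
   Gibbs scheme stalls in the funnel when a group SD approaches zero — the
   regime the degenerate-hierarchy tests target.

Defaults: 4 chains × (1000 warmup + 1000 draws); the test and acceptance
configurations use 2 chains × (400–600 warmup + 400–700 draws), sizes chosen
so the recovery suite's coverage estimates are stable. Convergence is
summarized by split R-hat and effective sample size on all condition-level
parameters (arviz); failures warn and set `converged = False` but draws are
always returned. Sweeps consume pre-generated random numbers, so a fit is
bit-reproducible from its seed.

Condition summaries marginalize over non-focal factors by the unweighted
per-draw mean of the relevant cell means (the design is balanced), and the
three contrasts — study time on drift, change probability on logit bias,
urgency on log boundary — are per-draw differences (manipulated − baseline)
of those marginal means, summarized with the central 95% credible interval;
a contrast is "credible" when that interval excludes 0. Refitting per margin
would be an alternative to per-draw averaging; per-draw averaging is exact
under the joint posterior and costs nothing.

## Synthetic cohorts

The generator emulates the ambulatory study design: 16 versions over 8 days
(two per day), participant orderings drawn from a pool of 3 schedule
permutations (assigned uniformly at random — whether the original schedules
were counterbalanced is not documented), exact trial compositions per
version (30/30 or 12/48 same/different in 60 trials; the composition is
fixed, not Bernoulli), person-condition parameters built as condition means
plus person-level offsets on the sampling scales, ages truncated-normal
(49 ± 14, range 24–80), and the person drift offset constructed jointly with
age to hit a target correlation (default −0.45). Default condition means are
the magnitudes reported for this task family (e.g. logit-bias +0.15 and log
boundary −0.05 effects in the single-probe version), so recovery tests
exercise realistic effect sizes.

Data-stream imperfections: whole sessions dropped with probability 0.0845
(matching the observed unrecorded-trial rate; missingness is session-level
because real noncompletion happened by whole versions, with a trial-level
knob defaulting to 0); responses exceeding the version's deadline recorded
with `response = none` and no RT; and a small fraction (default 54/59,762)
of responded trials replaced by contaminant RTs drawn uniformly from ranges
strictly outside the 200–7000 ms retention window (fast contaminants
anywhere, slow ones only where the deadline allows), so planted-count
bookkeeping tests are exact.

What the generator does **not** emulate: strategy use (e.g. encoding only 2
of 3 shapes), practice or time-of-day effects, trial-to-trial parameter
variability (the full Ratcliff model's s_v, s_z, s_t are out of scope), and
RT contamination inside the retention window. Passing recovery tests
therefore demonstrates estimator correctness under the assumed data law, not
robustness to these real-data features.

## Preprocessing conventions

"Faster than 200 ms and slower than 7000 ms" is read as strict inequalities:
exactly 200 or 7000 ms is retained (configurable). Deadline exclusions are
counted before RT-bound exclusions so no trial is double-counted. Report
percentages use scheduled trials as the denominator. A version counts as
completed when at least one of its trials was recorded.

## Posterior predictive checks

For each replicate, one posterior draw's person-condition parameters simulate
a full dataset under the observed design — same persons, cells, trial counts
and truths — followed by the same deadline censoring and RT-bound retention.
Observed RT quantiles at levels {0.1, 0.3, 0.5, 0.7, 0.9} (a standard
RT-quantile convention), split by response correctness per condition, are
compared with across-replicate medians and central 95% bands; the coverage
score is the fraction of observed quantiles inside their bands.
Condition × correctness cells with fewer than 5 observed trials are flagged
and skipped (order-statistic quantiles are unstable there). Quantiles use
linear interpolation of order statistics throughout, so tables are
bit-stable. Defaults: 6000 replicates for analysis runs, 200 in tests, where
the coverage score is already stable to ±0.02.

## Bayesian correlation

The population correlation ρ gets a stretched-beta prior on (−1, 1) with
shape 1/width; the default width 1 is a uniform prior, matching the default
of standard Bayesian statistics software. BF₁₀ integrates the reduced
likelihood of ρ given (n, sample r) — exact for bivariate-normal data up to a
ρ-free constant — against that prior by adaptive quadrature (relative
tolerance 1e-6), normalized by the likelihood at ρ = 0; the credible interval
comes from the normalized posterior on a fine grid. Exactly collinear data
return BF₁₀ = ∞ with a degenerate interval. Person-level parameter values
for the scan are posterior means of person-condition parameters averaged over
the grouping's conditions; propagating full posterior uncertainty through the
correlation is out of scope.

## Problem sizes and known limitations

- The recovery suite runs 10 seeded cohorts of 20 persons × 4 single-probe
  conditions (change probability × urgency) × 60 trials, 2 chains ×
  (500 + 600) iterations — sizes at which coverage estimates are stable and a
  full run stays inside a desktop time budget; the acceptance script uses 5
  seeds. The contrast-power and age-correlation checks run once at the
  study's 68 participants.
- Recovery cohorts disable deadline censoring. With the 3000 ms deadline
  active, discarding deadline-exceeding trials right-truncates the RT
  distribution, and a likelihood that ignores the truncation (this one, like
  the original analysis design it follows) underestimates the urgent-cell
  log-boundary by roughly 0.04 — the size of the urgency effect itself.
  Estimator calibration is therefore assessed on uncensored data; the
  truncation bias is a real limitation of the deadline design for
  boundary-separation inference.
- Group SDs cannot concentrate below the per-person measurement noise floor;
  with 60 trials per cell the logit-bias SD posterior resolves zero
  between-person variance only with enough participants (the degenerate
  hierarchy test uses 40).
- The Metropolis-within-Gibbs sampler yields lower effective sample sizes per
  draw than gradient-based samplers; split R-hat on short test-scale chains
  often sits slightly above the strict 1.01 default threshold. Diagnostics
  are reported honestly and analysis-scale runs should use the full default
  chain lengths.
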