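# Methods

## The task and its design

The package models a three-phase transitive-inference (TI) session over a
seven-item ordered list A–G (rank 1 = A, always correct against any later
item). Phase 1 massively trains the last pair FG (40 trials for the macaque
profile); phase 2 presents the 15 pairs comprising all adjacent pairs plus
every pair containing F or G (20 presentations each, 300 trials); phase 3
presents all 21 pairs (420 trials), for 760 trials per macaque session. The
human profile halves every presentation count (20/150/210, 380 trials, a
single session). Within each phase the pair multiset is shuffled uniformly
(the simplest scheme consistent with random counterbalancing; blocking is
not modeled but the shuffle is isolated in one function if a blocked variant
is ever needed), and the correct item appears on each side exactly half the
time, which requires even presentation counts and is enforced.

Each pair carries two orthogonal coordinates: symbolic distance (absolute
rank difference) and joint rank (rank sum). Over the 21 pairs the map
pair → (distance, joint rank) is injective, so the two can serve jointly as
regression inputs without collinearity; grid cells whose coordinates violate
the parity/bound constraints correspond to no pair and are reported as
interpolated regions only.

## Agent simulators (synthetic cohorts)

No public trial-level datasets exist for this design, so cohorts are
simulated from two minimal agent families that instantiate the two competing
accounts of TI. Their purpose is to generate data with the qualitative
structure the analyses must detect — not to fit real animals.

**Associative agent** (delta-rule value learner). Each stimulus carries a
scalar value, initialized at `v0 = 0.5`. Choice is a softmax on the value
difference with inverse temperature `beta` (default 5); the chosen item's
value moves toward the obtained reward (1/0) at rate `alpha` (default 0.2);
with `theta > 0`, a rewarded winner leaks a fraction of its value to its
partner (value transfer). After massed FG training the value of F approaches
1, so this family predicts a bias *toward* F when F first meets a novel
stimulus: first-xF accuracy below chance.

**Representational agent** (noisy ordinal positions). Each stimulus has an
internal position estimate; a choice samples each position with Gaussian
noise (`position_noise`, default 0.8) and picks the item read as earlier.
Feedback pushes the correct item earlier and the incorrect one later until
they are separated by `margin` (1.0), at rate `learn_rate` after correct
choices and `relearn_rate` after errors. Two additional ingredients:

- `massed_prior` ∈ [0, 1]: stimuli first seen during the massed phase are
  initialized toward the tail of the position line (the cross-session task
  knowledge that massed-phase items rank late). Monkey-like configuration
  uses 0.8, giving above-chance *avoidance* of F on the very first xF
  trial; task-naive human-like configuration uses 0, giving a transient F
  preference that a large `relearn_rate` (0.8) reverses within a few xF
  presentations.
- `repeat_boost` (0.5): position noise shrinks when the previous trial
  showed the same pair — a one-trial memory trace. Massed blocks therefore
  run at reduced noise, which produces high phase-1 FG accuracy and a step
  drop in FG accuracy the moment phase 2 interleaves other pairs, without
  any change to the learned positions.

Monkey-like defaults (`learn_rate` 0.05) learn an order of magnitude slower
than human-like defaults (0.5), matching the intended species contrast.

A third, parametric generator draws correctness directly from a caller-
supplied probability law; it is used wherever a known ground truth must be
recovered (linear log-odds trends, planted distance effects). Planted
effect sizes in the recovery tests are chosen to sit well above the
estimator's noise floor at the simulated cohort sizes (per-pair posterior
sd of the rate is roughly 0.001–0.006 log-odds/trial at 25–40 sessions), so
the tests measure recovery rather than statistical power.

Reaction times are generated independently of choice as
log RT ~ N(mu0 + distance_slope·distance + practice_slope·trial, sigma²).
Species baselines: mu0 = −1.35 (median 0.26 s) for macaques with no
practice trend; mu0 = 0.5 (median 1.65 s) for humans with a steady
within-session speed-up (−5·10⁻⁴ log-units/trial) and a clearer distance
effect. The human speed-up is linear in log RT; no asymptote is modeled.

## Gaussian-process analyses

Accuracy and log RT are treated as latent functions of trial index under a
squared-exponential (SE) kernel with one automatic-relevance lengthscale
per input dimension. The SE choice gives smooth, infinitely differentiable
curves, which the learning-rate analysis requires.

**Observation models.** Correct/incorrect flags are aggregated across
sessions into binomial counts per unique trial index (at most 760 unique
inputs per session layout), which makes exact O(n³) inference tractable
without sparse approximations and changes no estimand. The binomial
likelihood uses a logistic link with a zero prior mean — latent 0 is chance
(p = 0.5), appropriate for a two-alternative task — and the latent posterior
is a Laplace approximation at the Newton-located mode (tolerance 1e-8 on
the latent change, max 100 iterations; non-convergence raises with
diagnostics rather than returning a partial fit). Log RTs are exact
conjugate Gaussian regression with the sample mean as prior mean;
replicates at one trial index are averaged with noise variance scaled by
1/count (sufficient-statistic aggregation).

**Intervals.** 80% and 99% credible intervals are latent-Gaussian quantiles
mapped through the link, so probability intervals always lie in [0, 1] and
the 80% band nests strictly inside the 99% band. The reported probability
mean is the posterior expectation of the logistic (40-node Gauss–Hermite).

**Learning rates.** The derivative of the latent log-odds accuracy at a
phase's first trial is jointly Gaussian with the latent at the training
points; its mean and variance follow from the ∂k/∂x cross-covariances of
the SE kernel, with units log-odds per trial. A finite-difference check and
a small-n grid-integration oracle validate both paths in the tests.

**Hyperparameters.** Defaults are heuristic (signal variance 4, lengthscale
= span/4, jitter 1e-8) and sufficient for display curves. Optional
marginal-likelihood optimization (L-BFGS-B in log-space, multi-start,
never returning a value worse than the initializer) is available
everywhere. For binomial fits the optimized signal variance is capped at
36 (latent sd 6): log-odds beyond ±6 are observationally
indistinguishable, and with saturated counts the marginal likelihood
otherwise favors unbounded amplitudes, which destabilizes edge
derivatives. When pairs are *ranked* by learning rate, one kernel is
optimized for all pairs jointly (summed log marginal likelihood of
independent per-pair GPs, `optimize="shared"`): the GP derivative at a
phase boundary is attenuated by an amount that depends on the lengthscale,
and sharing the kernel keeps that attenuation comparable across pairs.

**Phase-transition profile.** The presentation-by-presentation analysis
around the phase 1→2 boundary uses Beta-binomial posteriors with a uniform
prior per within-session presentation index (last four phase-1 FG trials;
first six phase-2 instances of FG, xF, xG), pooled across sessions. A
6-point ordinal axis does not call for a GP. For FG and xF slots the
counted event is "chose F"; for xF that event is an error, so accuracy
views flip the Beta posterior. Missing presentation slots are reported as
truncated, never silently zero-filled.

**Joint surface.** A single GP over (trial, distance, joint rank) — fit
separately for accuracy and log RT, with independent hyperparameters — is
evaluated at the first phase-3 trial over an interpolation grid and at the
21 pair coordinates. Trial indices are binned within phase (default 20
trials/bin, bin-mean coordinate) to keep the unique-input count near ~670.
Effect summaries are the Spearman correlation of the pair estimates with
distance and the terminal-item contrast (pairs containing A or G minus the
rest), with Monte-Carlo intervals from independent latent marginal draws
(joint draws would need the full predictive covariance; marginal draws are
conservative for these rank/contrast statistics and far cheaper).

## Determinism

Every stochastic step flows through an explicit `numpy` Generator seeded
from user-supplied integers (`SeedSequence.spawn` for per-session
substreams); identical configurations reproduce identical datasets,
tables, and summaries.

## Problem sizes used in the shipped checks

Cohort-level checks run at 3 subjects × 20 sessions (macaque-like), 33
subjects × 1 session (human-like), 25–40 sessions for planted-effect
recovery, and 100 replicates for CI calibration — sizes at which the
qualitative signatures are decisively resolved by the Beta/GP posteriors.

## What passing these checks does and does not show

The synthetic generators reproduce the *structure* the analyses assume
(binomial choice counts, log-normal RTs, massed-phase priors, distance
effects), so green checks demonstrate that the machinery detects such
structure when present and stays calibrated under known ground truth. They
cannot certify conclusions about real macaques or humans: the agents omit
motivation, session-to-session drift, stimulus-specific salience,
working-memory limits beyond a one-trial trace, and any RT–accuracy
coupling. Known smaller gaps: the human-like agent's FG accuracy dips at
the phase-2 boundary (real participants stayed near ceiling), because
margin-based updates keep jostling F and G during interleaved training;
and the representational agent's first-xF avoidance is stronger than the
modest above-chance levels typically reported.
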