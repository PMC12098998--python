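# Methods

## The decision problem

On every trial an agent faces an offer `o_t` (points at stake) and a cost
`c_t` (points charged for acting).  Acting succeeds with a
stimulus-specific Bernoulli probability unknown to the agent; staying
passive forfeits the offer (robber framing, gains) or accepts the loss
(factory framing, losses).  Both framings give the same go-minus-no-go
value difference `ΔQ_t = p·o_t − c_t` for a subjective success
probability `p`, which is why a prior belief about `p` can in principle
generalise across the two tasks; the framings differ in the absolute
utilities and, empirically, in how often agents act.

## Task structure

A block has 60 trials: the 20 offer magnitudes
`round(50 / [0.10, 0.15, …, 0.95, 1, 2])` (round half-up) crossed exactly
once with each of 3 cost regimes.  Costs are
`round(set_cost + pct·offer)`: robber regimes (10, 15 %), (40, 5 %),
(75, 0 %); factory regimes (0, 10 %), (50, 5 %), (100, 0 %).  Twelve
stimuli carry the success probabilities `k/13, k = 1..12` (7.69 %–92.31 %)
and appear in consecutive runs with encounter counts
{4,4,4,4,4,4,5,5,5,6,7,8}.  The counts are counterbalanced by splitting
into two fixed lists A = {4,4,4,5,5,8} and B = {4,4,4,5,6,7} (each
summing to 30 trials), shuffling within each list and concatenating —
one concrete reading of "balanced over the block"; any equal-sum split
would satisfy the same intent.  Practice blocks have 18 trials, four
stimuli with encounter counts {4,4,4,6} and success probabilities
{0.8, 0.2, 0.5, 0.5}; practice stimulus ids are offset by 100 so they can
never collide with main-block stimuli.

Each block derives from a single seeded generator with a fixed draw
order (probability assignment, run-length shuffles, offer-cost shuffle),
so designs are bit-reproducible.  Costs are rounded to integers because
participants see integer point values; the offer-cost crossing survives
rounding with all 60 pairs distinct.

## Models

All models choose via `P_t(go) = logistic(ΔQ_t / τ)`.

* `softmax_only` (τ): assumes success is certain, `ΔQ = o − c`.
* `wsls` (τ, γ⁺, γ⁻): certain success plus a bonus `+γ⁺` after an active
  success or malus `−γ⁻` after an active failure on the immediately
  preceding trial.  The flags are stimulus-independent, reference only
  the previous trial, and reset at block boundaries (a passive trial
  clears both).
* `static_prob` (τ, p): one subjective probability for every stimulus.
* `bayes` (τ, μ₀, σ₀²): a Beta prior with mean μ₀ and *relative* variance
  σ₀² (beta variance divided by its bound μ₀(1−μ₀), so both moments live
  in (0,1)); `α₀ = μ₀(1/σ₀² − 1)`, `β₀ = (1−μ₀)(1/σ₀² − 1)`.  Active
  outcomes increment α (success) or β (failure) for that stimulus;
  passive trials change nothing; the posterior mean `α/(α+β)` enters ΔQ.
  Beliefs revert to the prior with each new stimulus; the
  `bayes_between_stim` variant instead carries a single posterior across
  stimulus changes (still resetting at task/block boundaries).
* Bias (`*_bias`) variants mix in a lapse φ ∈ (−1,1):
  `P(go) = [φ]₊ + (1 − |φ|)·logistic(ΔQ/τ)`, so φ > 0 is an action bias
  and φ < 0 a passivity bias.  For gradient-based fitting the rectifier
  is replaced by `softplus_α(φ) = log(1 + e^{αφ})/α` with α = 100 and |φ|
  by `softplus_α(φ) + softplus_α(−φ)`; the surrogate deviates from the
  exact rule by at most `log 2 / α ≈ 0.007`.  Simulation uses the exact
  rectified rule.
* Joint two-task models fit both tasks at once with task-specific
  temperatures τ^R, τ^F and a factory-only bias φ^F; `joint_1prior`
  shares (μ₀, σ₀²) across tasks, `joint_2prior` estimates them per task.
  Beliefs never cross the task boundary.

Parameters are estimated on an unconstrained scale: τ = 0.01·exp(θ)
(the 0.01 factor makes small temperatures easy to reach), γ = exp(θ),
unit-interval parameters are logistic transforms, φ = 2·logistic(θ) − 1.
Constrained values are clipped to lie strictly inside their open
supports (logistic saturates exactly in float arithmetic near |θ| ≈ 37,
which optimiser line searches do probe).  Choice probabilities are
clipped at 1e−12 before logs so likelihoods stay finite.

The likelihood evaluator is vectorised: under conjugate updating the
belief trajectory depends on the data only through per-trial counts of
earlier successes/failures, which are precompiled once per subject
(`TrialArrays`); the tests verify this path against an independent
trial-by-trial enumeration to 1e−10.

## Fitting

Per subject and model, the MAP minimises
`NLL(θ) + ½Σ(θ − m)²/v` with the default prior m = 0, v = 6.25.  The
optimiser (L-BFGS, numerical gradients) is launched from ten starts: a
data-scale heuristic whose temperature coordinates equal
`log(median|0.5·o − c| / 0.01)` (≈ τ of 20–40 points), the prior mean,
and unit-Gaussian perturbations of the heuristic.  Starting all
temperatures near θ = 0 (τ ≈ 0.01) would saturate every choice
probability and leave the objective locally flat, so the heuristic
anchor is essential, not cosmetic.

Log evidence uses the Laplace approximation
`log Z ≈ −NLL(θ*) + log N(θ*|m, v) + (d/2)·log 2π − ½·log det H` with H
the central finite-difference Hessian (step 1e−4) of the negative log
posterior, eigenvalue-floored at 1e−8 before the determinant.  For a
quadratic objective this is exact (tested).  Fit quality is reported as
pseudo-r² `= 1 − LL/(n·ln ½)`.

The hierarchical refinement is a deliberately simple empirical-Bayes
analogue of hierarchical Bayesian inference over models, not a
re-derivation of any specific toolbox: responsibilities
∝ exp(log evidence) per subject; group mean/variance per model are
responsibility-weighted moments of the subject MAPs (variance floored at
1e−4); subjects are refitted under the updated group Gaussian
(warm-started); iteration stops when the largest group-mean change is
below 1e−4 or after 50 rounds.

## Model selection

Random-effects selection uses a variational Dirichlet posterior over
population model frequencies (uniform Dirichlet(1) start).  M.freq is
the Dirichlet mean; exceedance probabilities come from ≥1e5 seeded
Monte-Carlo draws of the posterior; the Bayes omnibus risk compares the
variational free energy of the random-effects model against the fixed
equal-frequency null, `BOR = 1/(1 + exp(F₁ − F₀))`; and
`PXP = (1 − BOR)·XP + BOR/K`.  PXP is invariant to adding per-subject
constants to all models' evidences, and under exchangeable evidences BOR
→ 1 drives PXP to 1/K (both tested).

## Synthetic cohorts — what they emulate and what they do not

`simulate` reproduces the study's generative structure exactly: fresh
seeded designs per subject, sequential choice sampling, outcomes drawn
only on active choices, per-subject random streams spawned from a master
seed.  Default group distributions on the unconstrained scale are
Gaussian with SD 1; means are 0 for all parameters except the
temperature, whose mean is `log(10/0.01)` (median τ = 10 points).  With
median |ΔQ| around 25–37 points this puts agents in a value-driven but
clearly stochastic regime; a mean of 0 would give τ ≈ 0.01 and fully
deterministic choices, which neither resembles human data nor permits
gradient-based fitting.  Synthetic agents comply perfectly with the
generating model: no attention lapses beyond the modelled φ, no
reaction-time structure, no dropout, no session effects.  Passing
recovery tests therefore bounds what the *method* can do under ideal
conditions; they do not certify the models against real behaviour.

## Analysis scales

Desk-scale defaults keep every analysis on one CPU within minutes and
are the package's own choices: model recovery uses 20 repeats of
50-subject cohorts with 240 trials each (4 blocks) and 4 optimiser
restarts per recovery fit (the subject-level default remains 10);
parameter recovery uses 100 subjects.  At these scales the Bayesian
learner is selected over the softmax-only account in 100 % of repeats
and μ₀ is recovered with r ≈ 0.98.  Full-scale replications (hundreds of
repeats, larger cohorts) are configuration changes, not code changes.

## Psychometrics

ICC(2,1) (two-way, absolute agreement, single measure) is computed from
the ANOVA mean squares with the standard F-based 95 % interval; a
constant matrix returns 1 by convention with a warning.  Reliability is
meant to be computed on unconstrained parameters, where the fitting
prior is Gaussian.  The Spearman permutation test uses average ranks,
two-sided counting, and the add-one correction
`p = (1 + hits)/(1 + n_perm)` so p can never be exactly zero.

## Known limitations

* The Laplace evidence can be optimistic for strongly non-Gaussian
  posteriors (e.g. lapse parameters near their bounds).
* The empirical-Bayes group step shares the structure, but not the exact
  numerics, of full hierarchical Bayesian inference; evidences entering
  model selection are subject-level Laplace values.
* A stimulus-specific Q-learning variant is intentionally absent: in
  designs of this shape it is not identifiable against the Bayesian
  learner and static-probability models.
* `static_prob` is the σ₀² → 0 limit of `bayes`; at very small σ₀² the
  two are empirically indistinguishable, so confusion between them at
  that boundary is expected, not a bug.
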