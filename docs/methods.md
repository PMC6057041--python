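# Methods

This note records the models implemented in `caremcda`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
generators do and do not emulate.

## Value model

The framework is a multi-attribute *value* model for exactly two
alternatives: an integrated-care programme (*a*) and its comparator (*b*).
For criterion *j* with raw performance x_aj, x_bj ≥ 0 (not both zero),
standardization is by vector normalization

    S_aj = x_aj / (x_aj² + x_bj²)^½ ,

which removes scale differences between criteria while preserving the ratio
of the two arms' performance. For cost-direction criteria (higher raw value
worse: total costs, mortality, re-admissions, …) the complement
S = 1 − x/‖(x_a, x_b)‖ is used, so a lower cost scores higher; this is the
reading forced by the worked example's costs row (8000, 6000 → 0.20, 0.40).
Benefit criteria satisfy S_a² + S_b² = 1 exactly; cost criteria the
complemented identity. The overall value is the weighted sum
V = Σ_j w_j S_j with w on the unit simplex, so V ∈ [0, 1], and the higher-V
alternative is preferred (ties declared within 10⁻¹²).

Conventions:

- Aggregation always uses unrounded standardized scores. The worked
  example's overall value 0.722 is only reproducible this way (rounded
  2-dp inputs give 0.721); printed 2-dp/3-dp values are display rounding.
- The pairwise formula does not generalize to three or more alternatives
  without changing its meaning; tables with more than two alternatives are
  rejected rather than silently renormalized.
- Raw scores must be nonnegative and the (0, 0) pair is a hard error: the
  normalization is undefined there, and no imputation is attempted.

Criteria are defined at concept level with an explicit Triple-Aim category,
value direction, and worst/best scale range. The core-set ranges follow the
worked example (0–100, 0–100, 0–4, 1–5, 0–4, 1–4, 1–5; costs with
configurable currency bounds defaulting to 8500 worst / 5500 best).
Programme-type-specific outcomes are named concepts without published
numeric scales; the shipped catalog declares 0–100 defaults (reversed for
cost-direction ones) that are expected to be overridden from a catalog file
once real instruments are mapped. Utilisation-style supplements
(mortality, re-admissions, falls, justice contacts, caregiving and
medication burden) are modelled cost-direction because higher is
unambiguously worse; "living at home" is a benefit.

## Swing weighting (SMARTER)

A respondent imagines a programme at the worst level of every criterion and
repeatedly names the criterion they would swing to its best level next,
yielding a complete, tie-free ranking (the protocol removes one criterion
at a time, so ties cannot arise; tied input data are rejected rather than
fractionally ranked). Rankings become weights with the
rank-ordered-centroid rule w_k = (1/K)·Σ_{i=k..K} 1/i — the expected k-th
largest coordinate of a uniform simplex draw — implemented both in floating
point and in exact rational arithmetic (the latter serving as the test
oracle). A rank-sum rule is available behind a flag. Group weights are the
arithmetic mean of individual ROC vectors, renormalized (the SMARTER
convention; median available as an option). Swing weighting covers the core
plus programme-type-specific criteria in a single ranking; DCE weights
cover only the 8 core criteria, and the two weight sets are kept separate
with explicit provenance because they are not comparable.

## Discrete choice experiment

Choice tasks present two hypothetical programmes described by their level
(poor / average / good) on each of the 8 core criteria. Cost levels are the
country mean total health and social care cost ±20% (poor = 1.2·mean,
good = 0.8·mean); the cost attribute is then treated as a categorical
3-level attribute like the others, not as continuous currency.

**Coding and model.** Levels are dummy-coded against the poor reference, so
each attribute contributes two coefficients (average, good) and the model
has 16 parameters. Choice is binary logit on the utility difference:
P(A) = logistic(V_A − V_B), V = sum of level coefficients; attributes at
identical levels in both alternatives cancel. Under this coding the
good-level coefficient *is* the poor-to-good swing utility, which is why
criterion weights are derived as w_j = β_j,good / Σ β_good. A negative
good-level estimate contradicts the monotone framing of the elicitation and
raises an error telling the analyst to review signs rather than silently
flipping them. Respondent-level heterogeneity is not modelled (plain
conditional logit, not mixed logit): the target of inference is group-level
weights.

**Estimation.** Maximum likelihood by damped Newton iterations with
step-halving (the log-likelihood never decreases), covariance as the
inverse observed information at the optimum. Convergence is declared when
the gradient max-norm falls below 10⁻⁸ *or* the Newton step would change no
coefficient by more than 10⁻⁸ — at tens of thousands of observations the
log-likelihood's floating-point granularity caps the attainable gradient
norm, and the step criterion bounds the coefficient error far below any
reported precision. Fully-overlapped (inestimable) attributes and separated
data raise named errors instead of returning garbage.

**Design.** The design is 10 sub-designs × 18 paired choice sets, each
sub-design blocked into 3 blocks of 6 questions; a respondent answers one
uniformly assigned sub-design. Every choice set overlaps on exactly 4 or 5
of the 8 attributes (reduced cognitive burden at the cost of per-set
information). Search is greedy coordinate exchange: starting from a random
constraint-satisfying design, single-attribute level swaps are accepted
when they strictly reduce the local D-error det(I(β₀))^(−1/p), with
I = Σ_sets p(1−p)·Δx·Δxᵀ at a point prior β₀. Each set's overlap count is
drawn 4 or 5 with equal probability at initialization and preserved as a
hard constraint during exchange — without that, greedy search collapses
every set to the more informative 4-overlap extreme. The search is
deterministic given its seed. A Bayesian D-error over a prior distribution
is out of scope; the default prior is small positive monotone
(good 0.5 > average 0.25 > poor 0), and `update_priors` refits on
accumulated answers and re-optimizes once at least 50 respondents have
answered (below the threshold it returns the design unchanged, flagged).

## Uncertainty analysis

Deterministic sensitivity analyses: excluding a (typically dominating)
criterion with proportional renormalization of the remaining weights, and
swapping the weight source (DCE vs swing) with an agreement flag.

The probabilistic sensitivity analysis draws, per Monte-Carlo iteration:

- each performance mean from Normal(mean, SE) truncated to the criterion's
  scale range (degenerate at the mean when SE = 0), and
- the part-worth vector from MVN(β̂, Σ̂) using the estimated covariance,
  re-deriving weights per draw; for swing weights the uncertainty model is
  a respondent bootstrap of the rankings. Sampled good-level coefficients
  that come out negative are floored at zero before renormalizing — a
  per-draw error would abort the simulation — and a draw with no positive
  good-level coefficient falls back to uniform weights.

Each draw standardizes and aggregates exactly as the deterministic
pipeline, recording both overall values and both drawn mean costs. With all
SEs zero and zero coefficient covariance the PSA reproduces the
deterministic values bit-for-bit (both paths share the same floating-point
kernels in the same order).

The **CMAC** reports, for each budget threshold B on a strictly increasing
grid, the fraction of draws in which the intervention has the strictly
higher overall value *and* its budget impact is ≤ B. Budget impact defaults
to population_size × the draw's intervention mean cost, configurable to the
incremental cost versus the comparator; the population size and horizon are
required inputs, not assumptions. The curve is non-decreasing with limit
equal to the unconditional preference probability. The cost criterion stays
inside the value score by default even though it also drives the budget
condition (the worked example keeps it among the weighted criteria); a flag
removes it from the value score for analysts worried about double counting.

## Synthetic study generator

`TruthSpec` fixes true part-worths, true group weights, true two-arm means
and SEs, a population size, and a seed; all generators are pure functions
of (spec, seed).

- `simulate_trial`: observed means are truncated-normal draws around the
  true means with the declared SEs (exact at SE = 0). The zero-SE default
  regenerates the worked-example performance table cell for cell.
- `simulate_dce_responses`: each respondent gets a uniform-random
  sub-design and answers every set Bernoulli-logistically under the true
  part-worths.
- `simulate_swing_rankings`: each respondent ranks criteria by true weight
  plus Normal(0, noise_sd) perturbation on the weight scale (a Thurstonian
  model; a Plackett–Luce sampler would be the natural alternative), ties
  broken deterministically by criteria-set order.

Default truth: the worked example's performance table and the two
stakeholder weight vectors (P1, P2), with default SEs at 5% of each scale
range. The true DCE part-worths are an affine map of the P1 weights,
good_j = 0.5 + 2.0·w_j (range 0.6–1.1, average level at half the good
level). This preserves the example's importance rank order while placing
every poor-to-good swing utility in the range typical of fitted
stated-preference models (simulated choice consistency ≈ 70–80%); an
asymptotic information analysis shows this scale balances the two recovery
requirements — precise coefficients favour a small utility scale, precise
normalized weights favour a large total good-level mass — so that both are
met with margin at 600 respondents.

What the generators do **not** emulate: attrition and confounding in the
quasi-experimental performance estimates (the performance table is an
input, assumed already adjusted), respondent-level preference
heterogeneity, inattentive or lexicographic choice behaviour, and item
non-response. Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the stated models, not robustness to those
real-data features.

## Problem sizes and tolerances in the test suite

The suite exercises the full 10×18 design with 600 and 2400 simulated
respondents (coefficient MAE < 0.05 and per-criterion weight error < 0.02
at 600; both strictly shrink at 2400), a 10,000-draw PSA for CMAC
properties, and smaller 3×6 designs for unit-level checks. ROC weights are
checked against exact rational arithmetic to 10⁻¹²; standardization against
a direct per-cell re-evaluation to 10⁻¹²; the conditional logit against an
independent logistic-regression implementation (statsmodels) to 10⁻⁶ and
against a brute-force grid-search MLE on a tiny two-coefficient instance.
Monte-Carlo checks use the ½·n^(−½) bound on a proportion's standard error
with 3-SE slack.

## Known limitations

- Exactly two alternatives; the standardization is pairwise by definition.
- Local (point-prior) D-efficiency only; greedy exchange finds a good
  design, not a provably optimal one.
- Swing pooling assumes individual ROC vectors are exchangeable within a
  group; no respondent covariates.
- The PSA treats performance draws as independent across criteria (no
  correlation between outcome estimates from the same trial).
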