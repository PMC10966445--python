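# Methods

## The problem

Multimorbidity studies estimate, from a binary patient × condition matrix,
which pairs of long-term conditions (LTCs) co-occur more (or less) often
than chance. The standard measure, the relative-risk lift
RR_ij = N·N_ij/(N_i·N_j), is the observed-to-expected ratio of the
co-occurrence count. It is known to misbehave when counts are low: rare
condition pairs with a handful of co-occurrences receive extreme lift
values, their log-normal confidence intervals rest on asymptotics that do
not hold, and the resulting false positives compound in downstream network
and average-association analyses. This package implements a Bayesian
alternative — Association Beyond Chance (ABC) — alongside the RR baseline
and the downstream multimorbidity analytics, plus a synthetic-cohort
generator with known ground truth so that every estimator is testable
without access to clinical data.

## The ABC model

Each condition i has an independent-factor rate f_i ∈ (0, 1): the
probability that it appears through mechanisms unrelated to any other
condition in the panel. Each unordered pair (i, j) has a signed excess
f_ij attributable to shared mechanisms (common risk factors, one condition
promoting the other). The association measure is

    ABC_ij = 1 + f_ij / (f_i · f_j),

the ratio of shared-mechanism co-appearance to co-appearance by chance,
shifted by one so ABC = 1 means independence and the scale is directly
comparable to the lift. ABC > 1 indicates promotion, ABC < 1 inhibition.

### Likelihood

Writing p11 = f_i·f_j·ABC_ij for the probability of carrying both
conditions, the four cells of pair (i, j)'s 2×2 table get probabilities

    p11,   p10 = f_i − p11,   p01 = f_j − p11,   p00 = 1 − f_i − f_j + p11,

valid iff max(0, f_i + f_j − 1) ≤ p11 ≤ min(f_i, f_j). Each pair
contributes a multinomial over its four observed cells, and the model is
**joint**: one f_i per condition is shared by all pairs involving i, so
each pairwise association is informed by the condition's behaviour across
the whole panel rather than treated in isolation. The product over pairs
is a composite likelihood — the same patients appear in every pair — and
no correction for this reuse is applied; the practical consequences are
measured empirically (see *Calibration*, below).

### Priors

* log ABC_ij ~ Normal(0, σ_ABC), truncated to the feasible range by the
  parameterisation. Centred on independence, this is the source of the
  method's caution: pairs with little evidence are shrunk toward ABC = 1.
* σ_ABC ~ half-Normal(0.5) by default, or fixed by the user. Scale 0.5
  keeps most prior mass on associations weaker than e ≈ 2.7-fold while
  still reaching the strongest lifts seen in cohort studies; fixing a
  large value (≥ 5) effectively disables shrinkage and recovers the
  empirical lift in well-populated tables.
* f_i ~ Beta(μκ, (1−μ)κ) with μ ~ Uniform(0, 1) and κ ~ half-Normal(10):
  weakly informative, hyperprior-regulated, letting the panel's overall
  prevalence profile inform each rate without forcing it.

### Parameterisation and sampling

Sampling is over unconstrained variables: logit f_i, a per-pair u_ij
mapped onto the feasible p11 interval by a scaled logistic (so proposals
are feasible by construction; the Normal prior on log ABC is applied
through this transform with its Jacobian, without renormalising the
truncated mass), and logit/log transforms of the hyperparameters.

The posterior is drawn with the affine-invariant ensemble sampler
(`emcee`) over this density, using differential-evolution moves (80%
`DEMove`, 20% `DESnookerMove`), which mix far better than stretch moves at
the model's dimensionality (P + P(P−1)/2 + 3 parameters). Defaults: total
retained draws 20,000; walkers 2·(ndim+1) rounded to a multiple of the
chain-group count (4); warm-up 1,000 steps; thinning 5. Convergence is
reported as split-R̂ and bulk ESS computed over walker groups (via
`arviz`); a fit warns when max R̂ > 1.01. Divergence counts do not exist
for an ensemble sampler; the mean acceptance fraction is reported instead.
Runs are exactly reproducible under a fixed seed. Walkers start from a
small Gaussian ball around the empirical-moment point (smoothed
prevalences and joint frequencies), which removes the need for a long
exploratory warm-up.

### Summaries

Per pair: the mode, estimated as the midpoint of the shortest interval
containing 5% of the draws (an HPDI-midpoint estimator; 5% localises the
mode sharply at 20,000 draws and is configurable); a 99% equal-tailed
credible interval (0.5th/99.5th percentiles); and a significance flag set
when the interval excludes 1. Subgroup differences use the posterior
overlap p = 2·min(Pr(A>B), Pr(B>A)) over shuffled paired draws, ties split
evenly, with thresholds 0.05 and 0.01 both reported.

## The RR baseline

Point estimate N·N_ij/(N_i·N_j). Two interval methods are exposed:
`lift-delta` (default) places the log-normal interval around the lift
itself with delta-method SE √(1/N_ij − 1/N_i − 1/N_j + 1/N), so point
estimate and interval share one estimand; `katz-2x2` is the classical
Katz interval around the conditional risk ratio [a/(a+b)]/[c/(c+d)]. The
choice matters because "the Katz method" is ambiguous when the point
estimate is the lift; both are kept and the default is the internally
consistent one. The delta variance can go non-positive for very strong
positive associations (N_ij close to its margins); such intervals are
reported as undefined rather than patched. Significance is the two-sided
Fisher exact test (scipy) at α = 0.01, matching the 99% interval
convention. No continuity corrections anywhere; degenerate pairs (zero
margin or zero co-occurrence) are flagged and excluded from aggregation.
Between-stratum RR differences use a two-sided normal test on the
log-lift difference with delta-method SEs.

## Synthetic cohorts

Two modes behind one interface, both with closed-form implied truths
(marginals π_i and lifts L_ij) and root-finding calibration (tolerance
1e−9) of the requested lifts:

* **trigger** — per patient, condition i fires independently with rate
  g_i and each pair's shared trigger fires with rate s_ij, producing both
  conditions; the mechanism analogue of the ABC generative story. Closed
  forms: P(i absent) = (1−g_i)·∏_k(1−s_ik), and for a pair, P(both
  absent) = (1−g_i)(1−g_j)(1−s_ij)·∏_{k∉{i,j}}(1−s_ik)(1−s_jk); joint and
  lift follow by inclusion–exclusion. Shared triggers only add
  co-occurrence, so L_ij ≥ 1. The calibration alternates solving each
  s_ij (by Brent root-finding on the implied lift with marginals held on
  target) and resetting g from the marginal closed form.
* **copula** — a latent standard Gaussian vector with planted pairwise
  correlations, thresholded at per-condition upper-tail quantiles;
  negative correlations give lifts below 1, which the trigger story
  cannot produce. Calibration solves each ρ_ij from the bivariate-normal
  orthant probability; the resulting correlation matrix must be positive
  definite, which is checked.

Default prevalences are drawn log-uniformly over (0.001, 0.45), matching
the orders-of-magnitude spread of real LTC panels (hypertension-like
conditions near 45%, rare conditions below 0.1%). What the generator does
**not** emulate: age structure, deprivation, survivorship dynamics,
higher-order (beyond pairwise) dependence, and diagnostic misclassification.
Passing recovery tests therefore show the estimators work when the model
family matches the data-generating process; they do not certify behaviour
under real-data violations of that family.

## Networks and aggregation

Significant pairs (by either measure) become edges weighted by the
association value and signed by its side of 1; display width is the
absolute log weight. Community detection is Clauset–Newman–Moore greedy
modularity maximisation at resolution 1 on the unweighted graph of all
significant edges (a switch restricts to positive edges; how negative
edges should enter clustering is genuinely open, so both are available).
Ties in the greedy merge follow networkx's deterministic heap order under
the panel's node insertion order, so repeated runs agree. Partitions are
scored by modularity, coverage (within-cluster edge fraction) and
performance (correctly classified node pairs).

Average association of a condition: for ABC, the mean over its P−1 pair
draws is taken per posterior draw, yielding a distribution summarised by
median, IQR and 99% CrI — uncertainty propagates through the average
untouched; draws are not masked by per-pair significance. For RR,
non-significant and degenerate pairs contribute 1 (independence) and the
average is a point value, with an optional nonparametric patient
bootstrap (resample rows, recompute significance and average per
replicate, percentile interval).

## Problem sizes and numerical choices

The test suite and the acceptance script run the estimators at the scale
a desk study of the method needs: 6-condition panels of 10,000 patients
for recovery experiments (with 2,000–4,000 retained draws per fit when
many replicate fits are required), 50 replicates for interval-coverage
checks, and 10⁶ simulated patients for closed-form validation of the
generator. Exhaustive Fisher-test validation enumerates every 2×2 table
with N ≤ 16 and a seeded random sample of tables up to N = 60.

Degenerate inputs: all-zero conditions are retained in counting (their
pairs have N_ij = 0) but dropped from the ABC model of a stratum where
they have zero prevalence, with a logged notice, because their f_i is
unidentifiable there. Missing values in input matrices are rejected, not
imputed. Exclusion thresholds on rare conditions are deliberately not
applied anywhere — handling low counts is the point of the method.

## Calibration findings and known limitations

* 99% CrIs from the joint model cover generator truth in ≈ 94% of
  pair-replicates under the 6-condition recovery conditions — slightly
  below nominal, consistent with the uncorrected composite likelihood.
* The posterior-overlap subgroup test is anti-conservative in the joint
  model: with identical strata truths carrying real associations it flags
  ≈ 11–13% of pairs at the 0.05 threshold rather than ≤ 5%. The cause is
  measurable: across replicate datasets the sampling sd of the posterior
  mean exceeds the posterior sd by a factor of ≈ 1.2–1.6 per pair — the
  composite likelihood's patient reuse overstates precision. Two controls
  isolate it: the single-pair model (exact multinomial likelihood, no
  reuse) calibrates at exactly 5%, and a fully null truth yields 0%
  (shrinkage collapses all posteriors onto 1). Overlap p-values from
  joint fits should therefore be read as a screening statistic, and the
  0.01 threshold is reported alongside 0.05.
* RR delta-method intervals are undefined for extremely strong
  associations; Katz-2×2 intervals remain available there.
* Runtime grows quadratically in panel size through the pair count; a
  40-condition panel has 780 pairs and ~823 parameters, well within the
  ensemble sampler's reach but needing proportionally more walkers and
  steps.
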