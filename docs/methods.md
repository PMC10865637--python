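# Methods

## Study design and data model

The unit of analysis is an *annotation*: one clinician's binary prediction
(*hypoxia* / *normal*) for one delivery case. Ground truth is derived from
umbilical cord blood pH at birth: a case is hypoxic exactly when pH < τ, with
τ = 7.15 (moderate fetal hypoxia). pH exactly equal to τ is classed normal —
the definition is a strict inequality, and the generator keeps simulated pH
values clear of τ so rounding can never flip an outcome. Plausible cord pH is
bounded to [6.50, 7.60]; values outside are treated as data errors, not
clipped.

Participants carry a profession (resident, midwife — student midwives are
folded into midwives with an `is_student` provenance flag — or
obstetrician-gynecologist), years of experience since diploma, practice
setting and country. Experience is banded into [0, 2), [2, 4), [4, 8) and
[8, ∞) years. The bands are left-closed/right-open: the conventional "0–2,
2–4, …" notation is ambiguous at shared boundaries, and the half-open
convention guarantees every value maps to exactly one band (verified by an
exhaustive grid scan in the tests).

Stored derived columns (`true_outcome`, `experience_band`) are *validated*
against the recomputed values on read, never trusted; referential integrity,
id uniqueness, and gap-free 1..k presentation indices per participant are
checked with row-level error context.

## Case assignment

All participants see the same fixed sequence of batches of 10 cases, each
batch containing exactly 5 hypoxic and 5 normal cases; only the order within
a batch is randomized per participant. Consequences: annotation prevalence is
50% for any participant whose count is a multiple of 10, and light
annotators' case sets overlap heavily (they all start with batch 1), which is
what makes the consensus-based agreement analysis well populated.

Batch composition is drawn once by shuffling the hypoxic and normal pools
separately and taking 5 + 5 per batch. Batch order is fixed rather than
permuted per participant — the shared-batch design only guarantees case-set
proximity if everyone walks the batches in the same order. Within-batch
permutations come from counter-style streams keyed by
(seed, participant id, batch index) hashed through BLAKE2b, so a sequence is
reproducible in isolation and adding participants never perturbs existing
ones.

## Accuracy metrics

Success rate is the fraction of annotations matching the pH-derived truth;
sensitivity and specificity are the same fraction restricted to annotations
of truly hypoxic and truly normal cases respectively. Metrics pool
annotations (not participant averages), so the stratum n's equal annotation
counts and success numerators add across any disjoint grouping. A stratum
with no annotations of the relevant truth class reports that metric as
undefined (`None`), not zero.

Every proportion carries a Wilson score interval — the score-test inversion,
better behaved than the Wald interval at extreme proportions and small n:

    centre = (p̂ + z²/2n) / (1 + z²/n)
    half   = z/(1 + z²/n) · √(p̂(1−p̂)/n + z²/4n²)

with z the standard-normal quantile at (1 + level)/2, level 0.95 by default,
bounds clipped to [0, 1]. The tests cross-check the closed form against
statsmodels and against a brute-force root finder on the score inequality,
and verify ~95% empirical coverage at n = 30.

Between-stratum comparisons use an interval heuristic, not a hypothesis test:
two strata are flagged as (likely) different on a metric exactly when their
95% intervals do **not** overlap. This is conservative relative to a two-sample test and is reported as a
labelled flag.

Two plot-ready products: per-participant TPR/FPR operating points (each
reader is a single operating point, not a ROC curve), restricted to
participants with strictly more than 10 annotations and at least one case of
each truth class; and the success-rate profile over cord-pH ranges bounded by
the cut points 6.90, 6.98, 7.05, 7.13, 7.20, 7.28, 7.35, 7.43 (chosen for a
balanced case distribution), as half-open bins (−∞, t₁), [t₁, t₂), …,
[t₈, +∞).

Sample size uses Buderer's formulas, n_Se = z²·Se(1−Se)/(d²·prev) and
n_Sp = z²·Sp(1−Sp)/(d²·(1−prev)), returning the larger rounded to the
*nearest* integer. With Se = 0.45, Sp = 0.67, d = 0.14, prev = 0.5 the
formula gives 97.02; a ceiling rule would give 98, but nearest-integer
rounding reproduces the conventional answer of 97 for these inputs, and the
half-case discrepancy is immaterial at this precision.

## Agreement and reliability

Within each profession, each case annotated by at least one member receives
the most frequent label as the profession's consensus. Exact vote ties are
not a consensus: under the default `exclude` policy the case is dropped from
the vector (and recorded), with `hypoxia`/`normal` force-label alternatives
exposed in config.

For each profession pair, on the cases where both have a consensus
(*overlapping cases*):

* **PA** — agreement count / overlap, with a Wilson interval. Altman
  categories: ≤0.20 poor, ≤0.40 fair, ≤0.60 moderate, ≤0.80 good, ≤1.00 very
  good. A pairwise PA is additionally marked non-significant when its lower
  bound falls below 0.50.
* **κ** — from the 2×2 cross-table, κ = (p_o − p_e)/(1 − p_e); the interval
  uses the classic large-sample SE √(p_o(1−p_o)) / ((1−p_e)√N), clipped to
  [−1, 1]. Landis–Koch categories: ≤0.20 slight, ≤0.40 fair, ≤0.60 moderate,
  ≤0.80 substantial, ≤1.00 almost perfect. With a 50/50 design prevalence the
  two metrics are comparable (κ is prevalence-sensitive in general).

Values are rounded half-up to two decimals before categorization so that the
published scales' unprinted gaps (e.g. 0.805) resolve deterministically;
upper bounds of each printed range are inclusive.

The **overall** PA and κ are the n_overlap-weighted means of the pairwise
values. Their confidence intervals come from a case-level bootstrap (default
2000 resamples, stream keyed by the seed): cases are resampled with
replacement from the union of consensus cases, all pairwise statistics and
the weighted mean are recomputed per replicate, and percentile bounds taken.
A closed-form interval for this weighted composite would have to model the
dependence between pairs that share a profession; the bootstrap handles that
dependence directly. Replicates in which a pair loses its overlap or κ
degenerates drop that pair (or replicate) rather than biasing the mean.

Fleiss-style multi-rater kappa, weighted kappa and intra-observer
(test–retest) analysis are deliberately out of scope: labels are binary and
the procedure is defined on profession-level consensus vectors.

## Synthetic cohort generator

The generator emulates the statistical structure this analysis assumes, so
every stage is testable without access to any real annotation data, and it
supports parameter-recovery experiments against known truth.

* **Cases** (default 100): pH ~ Normal(7.20, 0.12) truncated to [6.85, 7.47],
  sampled separately below and at-or-above τ to force the exact 50/50 split;
  values rounded to 4 decimals and kept clear of τ. The truncation range is
  the plausible intrapartum cord-pH span; mean and SD are config, as real
  labor-ward pH distributions vary.
* **Participants** (default 120; 39 residents, 23 midwives, 58
  obstetrician-gynecologists): experience band from a (0.25, 0.20, 0.20,
  0.35) mixture with uniform years within band (8–25 in the top band);
  84% university-hospital setting; country France with probability 94/120.
  The experience mixture is a plausibility choice — nothing in the cohort
  description constrains it — and is config, not a constant.
* **Response model**: rater r predicts hypoxia with probability
  σ(a_r + b_r(τ − pH)). Bias a ~ Normal(0, 0.4); discrimination b ~
  log-normal(median 8 per pH unit, σ_log 0.5). This two-parameter logistic is
  the minimal model that reproduces both near-chance success for pH close to
  τ and high success at the extremes — the characteristic U-shaped
  success-by-pH profile. b = 0 is the chance limit (success 0.5), b → ∞ the
  noiseless limit (success 1).
* **Participation**: with probability 0.10 a rater annotates all 100 cases;
  otherwise a log-normal(median 9, σ_log 1.1) count truncated to [1, 99]. A
  single log-normal cannot simultaneously match a median near 11, quartiles
  near 5 and 36, and ~10% completers; the point-mass + truncated log-normal
  mixture can, and both components are config.
* **Streams**: every draw is keyed by (seed, entity ids), so adding a rater
  never changes existing raters' data and any subset is reproducible.

What the generator does **not** emulate: learning or feedback effects over a
session (each rater is stationary; the real tool revealed the answer after
every case), case-level difficulty beyond pH (signal quality, missing data,
maternal-heart-rate contamination), and correlation between profession or
experience and accuracy (latent parameters are drawn independently of
profession). Passing tests therefore demonstrate the pipeline's correctness
and calibration under this model, not claims about real clinician behaviour.

**Parameter recovery**: per rater, empirical Se/Sp with Wilson intervals;
for raters with ≥ 30 annotations, (a, b) by maximum-likelihood logistic
regression of the predicted label on (τ − pH) (statsmodels; non-converged or
separated fits are reported as NaN rather than guessed). The test-suite
oracle for recovery is the fixed-design Fisher information of the logistic
fit (numerical 2×2 information matrix over the actual case pH values), which
gives the asymptotic SE of b̂ without simulation.

## Problem sizes and numerical choices

The default test and acceptance runs use the generator defaults (100 cases,
120 raters, ~2.9k annotations), a 200-rater × 100-annotation recovery
experiment, 10⁴-draw coverage simulations, and 2000 bootstrap resamples —
sizes at which every Monte-Carlo check has comfortable margin while the whole
suite runs in well under a minute. Quartiles in the cohort-description table
use Tukey hinges (median-of-halves, the median shared by both halves at odd
n) by default, with linear interpolation as a config alternative — the two
differ at small per-profession counts and the convention must therefore be
pinned. Report CSVs round metrics to two decimals and percentages to
integers for display; the JSON mirrors retain full precision. Logistic
probabilities are computed with `scipy.special.expit` to avoid overflow in
the noiseless limit.

## Known limitations

* Consensus-level agreement overstates individual-level agreement: majority
  vote denoises each profession before comparison. The package computes what
  the design specifies; an individual-level analysis would need a multi-rater
  statistic.
* The large-sample κ SE is approximate at small overlaps; the bootstrap
  option exists for symmetry with the overall CI but pairwise CIs default to
  the closed form.
* The interval-overlap "significance" flag is a heuristic; non-overlap at
  95% is conservative evidence of a difference, overlap is not evidence of
  equality.
* Pooled sensitivity across strata is a weighted mean of stratum
  sensitivities (weights = hypoxic-annotation counts); a pooled value can
  never exceed every stratum's value.
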