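# Methods

## Problem setting

A two-level within-participant manipulation is applied to trial-level
outcomes (reaction times, accuracies, confidence ratings). The package
targets the *global null* hypothesis — no single participant's outcome is
sensitive to the manipulation — rather than the usual directional null of a
zero population-mean effect. A group of participants with real effects of
mixed sign violates the global null while satisfying the directional one,
which is exactly the case directional t-tests cannot see.

## Data model and eligibility screen

Input is a long-format table, one row per trial, validated into a
`TrialTable`: exactly two levels per condition factor (one optional second
two-level factor for interaction contrasts), finite numeric outcomes, every
participant represented in every condition. The declared level order fixes
the sign convention for every statistic (`value = positive level −
negative level`); it is an explicit user declaration, never file order, so
results are reproducible across differently sorted files.

The eligibility screen excludes a participant when (a) any condition cell
holds fewer than `min_trials = 5` trials, or (b) their outcome is constant.
The zero-variance rule is evaluated over *all* of a participant's trials,
not per condition: a participant constant in one condition but not the
other still carries information, and the global reading is the natural one
for a screen meant to remove degenerate records. Both rules are reported
per participant with a reason string, and `apply_exclusions` is idempotent.

## Per-participant statistics

All statistics are antisymmetric under swapping the condition levels:

* `mean_diff` — difference of cell means (outcome units).
* `cohen_d` — mean difference over the pooled SD with per-cell Bessel
  correction (the conventional two-sample *d*). No small-sample (Hedges)
  bias correction is applied by default; the tests compare like with like
  (observed vs. permuted), so the bias cancels in the comparison.
* `dprime_diff` — z(rate in positive cell) − z(rate in negative cell) for
  binary outcomes, with extreme rates 0 and 1 replaced by 1/(2N) and
  1 − 1/(2N), the standard signal-detection correction.
* `phi` — the 2×2 correlation of condition × binary response; errors on a
  zero margin.
* `auroc2_diff` — type-2 AUROC (confidence discriminating correct from
  incorrect trials) conditioned on one response minus the other. The AUROC
  is computed by the rank (Mann–Whitney) formula with half credit for
  ties, which equals the trapezoidal area over the observed confidence
  criteria. A participant whose response cell lacks correct or incorrect
  trials has no defined value and is dropped for this statistic with a
  logged reason.
* `interaction_contrast` — difference of simple effects on the four cell
  means of a 2×2 within design.

## Permutation engine

Both novel tests share one null construction. For each participant, M
(default 100) copies of their trials are made with condition labels
shuffled within the participant — preserving per-condition counts, and
shuffling within levels of the second factor when present so all four cell
counts survive. Each copy yields one statistic value, giving a
per-participant bank. B (default 10,000) group-level null samples are then
drawn, each the mean over participants of one bank value sampled with
replacement. This two-stage scheme (in the spirit of Stelzer et al.'s
aggregation of subject-level permutations) approximates the full
permutation distribution at a fraction of its cost; duplicated
permutations are permitted and only matter for very small trial counts.

The p-value uses the add-one estimator, (1 + #{null ≥ observed})/(B + 1),
which can never be zero and keeps the test valid. One master seed spawns a
stream per participant keyed by a stable sort of the identifiers, plus one
stream for the group stage (also consumed in sorted order), so identical
seeds give bit-identical results regardless of row order.

## Sign consistency

A participant's score is the proportion of `n_splits = 500` random
split-halves in which the statistic has the same nonzero sign in both
halves. Splits are stratified by condition cell — each half must contain
both conditions or the statistic is undefined; a cell of size m sends
⌊m/2⌋ trials to the first half. A split in which either half's statistic
is exactly zero counts as inconsistent: zero carries no sign, and this
conservative tie rule only matters for discrete outcomes. The same seeded
split schedule is reused for the observed data and for every permuted copy
of that participant, which removes schedule noise from the
observed-vs-null comparison and makes results reproducible.

For the default `mean_diff` statistic the score and its permutation bank
are computed by matrix products over the precomputed split masks, so a
full 15 × 100-trial test at M = 100, B = 10,000 runs in roughly a tenth of
a second; any other statistic uses a generic split loop (at ~M × n_splits
statistic evaluations per participant).

## Absolute effect size

Each participant contributes |s(i)| (default `cohen_d` for continuous
outcomes; `dprime_diff` and `phi` are the natural choices for binary
accuracy and response data). The permutation null recomputes |s| on the
shuffled copies — the same procedure as sign consistency, not an analytic
folded-null — so the two tests differ only in the participant-level score.
Under the global null with N_t trials per condition, d ≈ N(0, 2/N_t) and
the group mean |d| concentrates near √(2/N_t)·√(2/π) (≈ 0.113 at
N_t = 100), a useful sanity anchor.

## Prevalence global-null test

Stage one tests each participant two-sidedly at α_individual (default
.05): a two-sample t-test for continuous outcomes (the conventional
choice), or a within-participant label-permutation test on |statistic| —
exhaustive over all label assignments when there are at most 20,000 —
for outcomes where t is inappropriate (e.g. d′ effects; which individual
test to use there is genuinely open, so it is a constructor option).
Stage two refers the significant count k of n to Bin(n, α_individual):
p = P(X ≥ k). The prevalence CI is the exact one-sided Clopper–Pearson
inversion — the smallest π with P(X ≥ k | n, π) ≥ α_prevalence, i.e. the
α_prevalence quantile of Beta(k, n−k+1) — whose lower bound exceeds
α_individual exactly when p < α_prevalence. For k = 1, n = 15 this gives
p = 1 − .95¹⁵ = .537; for k = 12, n = 15 the lower bound rounds to 56%.

Because the second stage is a discrete binomial test, its attainable size
is below the nominal level: at n = 15, α = .05 rejection requires k ≥ 3
and the exact size is P(X ≥ 3 | 15, .05) ≈ .036. Calibration checks
therefore compare the Monte-Carlo rejection rate to this attainable size,
not to .05; the test is conservative, never anticonservative.

## Omnibus ANOVA

The F statistic is computed as a residual-sum-of-squares comparison of two
least-squares fits — participant × condition cell means (full) vs.
participant means (reduced) — rather than through a named ANOVA routine,
which sidesteps sum-of-squares-type ambiguity and handles unbalanced cells
naturally: df = (P(C−1), N − PC), so (15, 2970) for 15 participants × 2
conditions × 100 trials/cell. On balanced data this equals the joint OLS
test of condition plus participant × condition (cross-checked against
statsmodels in the suite). Normality and equal within-participant variance
are assumed and *not* relaxed; unequal variances are known to distort this
test badly, and no robust variant is offered.

## Simulator

`simulate_scenario` draws e_i ~ N(0, σ_b) and outcomes c·e_i + N(0, σ_w),
c ∈ {0,1} (c = 1 for the incongruent condition), with the two named
scenarios `non_directional` (σ_b = 15, σ_w = 30) and `global_null`
(σ_b = 0, σ_w = 100), both 15 participants × 100 trials per condition.
These defaults *are* the study conditions; the baseline offset defaults to
0 because every test is location-invariant. The generator emulates i.i.d.
Gaussian trial noise with homogeneous variance — it does not reproduce RT
skew (lognormal/ex-Gaussian shapes), sequential dependencies, or unequal
within-participant variances, so passing calibration here does not certify
behaviour under those violations (the parametric OANOVA is the test most
exposed to them).

`estimate_operating_characteristics` re-draws fresh latent effects every
replicate (the scenarios define distributions, not fixed effect vectors)
and reports the rejection proportion with an exact binomial CI.

## Numerical and design choices

* Group-statistic comparisons use a relative 1e-12 tolerance when counting
  null samples ≥ observed, so exact ties (common with discrete scores)
  count in favour of the null.
* The directional sign-flip test enumerates all 2ⁿ flip patterns for
  n ≤ 15 participants (exact p, identity pattern included) and falls back
  to 10,000 Monte-Carlo flips with the add-one correction above that.
* Bank sampling in the group stage is with replacement across the B
  samples, matching one-draw-per-participant-per-sample aggregation.
* Reported prevalence percentages are rounded for display only; raw
  fractions are kept in results objects.

## Problem sizes used in the checks

The test suite validates calibration with 1,000 global-null replicates at
B = 1,000 null samples per test (the binomial 95% acceptance region around
the attainable size), scenario reproduction with five seeds at the full
B = 10,000, and all oracle equivalences (exhaustive splits, exhaustive
label permutations, hand SSE decompositions, pairwise AUROC counts) on
participants small enough to enumerate. Scores under non-directional
differences are single-realisation quantities: their across-seed SDs are
roughly 5.5 percentage points (group SC) and 0.018 (global-null group
|d|), and the reproduction checks use 2.5-SD bands around the reference
values.

## Known limitations

* Only 2-level factors (at most two of them); no continuous covariates.
* No meta-d′ or parametric metacognition models; no Bayesian prevalence
  posterior; no heteroscedasticity-robust OANOVA.
* The generic (non-`mean_diff`) sign-consistency path is loop-based and
  costly for large M × n_splits.
* Non-directional findings are causally interpretable only when
  confounders (condition order, response mapping) are counterbalanced
  *within* participants; between-participant counterbalancing makes a
  counterbalanced nuisance factor indistinguishable from the manipulation.
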