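# Methods

## Model and procedure

The package tests whether two patient groups share the same joint
distribution over K mixed-type clinical variables. The global null is the
intersection of K per-variable distributional equalities; the alternative is
their union (at least one variable differs). Inference is conditional on the
pooled observed data: under the null the group labels are exchangeable, which
licenses permutation tests with exact finite-sample validity and no
distributional assumptions on the outcomes.

The pipeline has four stages:

1. **Partial tests.** Each variable gets a one-dimensional permutation test,
   significant for large values. Numeric variables use the unstandardized
   absolute mean difference |x̄₁ − x̄₂|; categorical variables use the
   likelihood-ratio statistic G = 2 Σ O log(O/E) of the 2×L group-by-level
   table (0·log 0 = 0; zero-total levels drop out). Both are referred to
   their permutation distributions, never to asymptotic χ² laws — the
   asymptotic G p-value is available only as a diagnostic via scipy.
2. **Assignment generation.** When C(n₁+n₂, n₁) is at most the
   `exact_threshold` (default 20,000), every distinct split is enumerated and
   the p-values are exact. Otherwise Conditional Monte Carlo draws B − 1
   uniformly random label shuffles plus the observed assignment. Duplicate
   splits are deliberately retained; deduplication would bias the estimator.
   The estimator counts the observed assignment in numerator and denominator,
   so p ∈ {1/B, 2/B, …, 1} and the smallest reportable raw p at B = 10,000 is
   0.0001. This makes the test slightly conservative, which is the standard
   trade for guaranteed validity.
3. **Nonparametric combination.** All K statistics are recomputed on one
   shared unit-level assignment sequence, preserving the joint dependence of
   the partial tests. Each column of the B×K statistic matrix is transformed
   to significance levels λ[b] (the within-column survival fraction); rows
   are collapsed by Fisher (default), Liptak or Tippett; the observed
   combined statistic is referred to its own permutation column. Fisher is
   the default because it is the literature's all-round choice with good
   power against diffuse alternatives; Tippett is better against sparse
   alternatives (one strong effect); all three are exposed.
4. **Multiplicity.** Holm's step-down rule is applied to the K partial raw
   p-values: reject ordered hypotheses while p₍ᵢ₎ < α/(K − i + 1). Adjusted
   p-values use the monotone cumulative-maximum form, so thresholding the
   adjusted values at any α < cap reproduces the sequential decisions
   exactly. This controls the familywise error rate under arbitrary
   dependence and dominates single-step Bonferroni.

## Missing data

Deletion is casewise **per variable**: a unit missing variable i is removed
from variable i's permutation sample space only, which is unbiased under
MCAR. When a shared assignment sequence is used, each variable restricts the
unit-level assignment matrix to its complete cases, so the permuted group
sizes of an incomplete variable vary slightly across assignments. This is the
closest feasible reading of jointly processed partial tests under
missingness: strict sharing is impossible once different variables retain
different units. Rows of a restricted assignment that would leave a group
empty contribute a statistic of 0 (no evidence against the null); this can
only occur in very small cohorts.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_permutations` (B) | 10,000 | CMC assignments incl. the observed one; raw p resolution is 1/B |
| `exact_threshold` | 20,000 | max #splits for exhaustive enumeration |
| `seed` | 0 | drives the single shared assignment stream |
| `method` | fisher | combining function (fisher / liptak / tippett) |
| `alpha` | 0.05 | familywise level of the Holm stage |
| `cap` | 1.0 | ceiling for adjusted p-values; 0.9999 mimics permutation software that saturates at (B−1)/B |
| `tie_tol` | 1e-12 (relative) | tie tolerance absorbing float jitter among permutations of identical sums |
| `studentize` | off | Welch-standardized numeric statistic, robust to unequal variances |

λ values are clamped into [1/(2B), 1 − 1/(2B)] before the Fisher log and
Liptak quantile transforms; the clamp keeps ψ finite at the boundaries and
cannot change any rank.

## Synthetic cohort generator

The generator emulates the sampling structure the analysis assumes, not the
full complexity of the real registry data: two independent groups, numeric
variables Gaussian with per-group (mean, SD), binary variables Bernoulli with
per-group proportions, all variables mutually independent, and an optional
MCAR mask at a per-cell rate. The built-in default model transcribes the
motivating study's published design — n₁ = 631, n₂ = 1091, and all 22
per-variable means ± SDs / percentages — and a null variant copies group-1
parameters over group 2 so the global null holds exactly.

What it does **not** emulate, because the published study quantifies none of
it: the 12-centre structure, inter-variable dependence (an optional
Gaussian-copula correlation matrix is provided for robustness experiments,
not as a calibrated default), non-negativity and skewness of ages, durations
and scores, structural missingness (therapy durations existing only for
treated patients), and the follow-up censoring process. Passing tests on
synthetic cohorts therefore validate the *inferential machinery* — size,
power trends, invariances — not distributional realism.

Two generator design choices were genuinely open:

* **Charlson comorbidity score.** An ordinal score generated as a
  zero-truncated integer-rounded Gaussian is available
  (`charlson_ordinal=True`), but the default keeps it continuous Gaussian:
  truncating N(1.47, 1.81) at zero would shift its mean to ≈ 2.12 and break
  the contract that generated moments match the declared parameters, which is
  what the mean-difference statistic consumes.
* **Binary orientation.** Each binary variable is parameterised by the
  probability of its first level ("yes", or M for gender, survivor for final
  exitus), taken as the first of the two published percentages per group.

## Numerical choices

* Ties: all p-value and λ counts use a relative tolerance of 1e-12 so that
  permutations producing mathematically equal sums compare equal despite
  floating-point noise. With the absolute mean-difference statistic and equal
  group sizes, every split ties with its complement; exact p-values on
  balanced designs are therefore multiples of 2/M.
* The identity assignment is always row 0; the observed statistic is read
  from that row, guaranteeing t_perm[0] = t_obs bit-for-bit.
* Degenerate variables (one observed level, or one group entirely missing)
  yield a flagged result with raw p = 1 and a warning rather than an error,
  so one pathological column cannot abort a K-variable analysis. A fully
  missing group, by contrast, is a hard error at extraction time.
* Holm ties are broken by stable sort on input order; adjusted values are
  unaffected (cumulative maximum), ranks are consecutive and deterministic.
* Rendering: a p-value at its 1/B floor prints as 0.0000 in table style
  (the convention of the permutation software the motivating study used —
  "below resolution", not literally zero); machine-style output carries full
  precision and round-trips exactly.

## Problem sizes used in the checks

The test suite and the acceptance script scale their simulations to what the
statistical question needs: exact-oracle equivalence uses cohorts with
n₁+n₂ ≤ 10 where full enumeration is trivially cheap; size control uses
1,000 global-null replicates of a 10-variable n = 60/100 cohort at B = 1,000
(the binomial 99% band around α = 0.05 at 1,000 replicates is ±~1.8
percentage points); effect recovery uses 100 replicates at the full design
sizes n = 631/1091 with B = 2,000, where the Monte-Carlo error of each raw p
is at most ~0.011 and irrelevant to Holm decisions at the observed effect
sizes.

## Known limitations

* The per-variable effect sizes implied by the published means ± SDs at the
  published group sizes do not reproduce the published raw p-values for every
  variable under independent full-sample Gaussian sampling; the durations of
  therapy, in particular, carry much stronger implied evidence than their
  published p-values, consistent with the originals being recorded only for
  treated patients. The generator follows the published descriptive
  parameters, so recovery experiments identify a Holm-significant superset of
  the published nine variables rather than that exact set.
* Only two groups are supported; no stratified or restricted permutations,
  no one-sided alternatives, no FDR-type procedures, no closed testing or
  weighted Holm variants, no imputation.
* CMC p-values carry O(1/√B) Monte-Carlo error; no sequential/adaptive
  stopping is implemented.
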