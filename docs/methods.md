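# Methods

This note records the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Report-table preparation

A spontaneous-report extract is four linked tables keyed by case id. The
preparation stage applies, in order:

1. **Deduplication.** Cases may be submitted repeatedly; the DEMO table
   carries a report version per submission. We keep the row set of the
   highest version per case id (latest submission wins) and collapse exact
   duplicate (drug, role) and event rows within the kept case. The
   operation is idempotent, and the removed-submission count is reported.
2. **Demographic recoding.** Age, height and weight arrive as decade-band
   codes; a band code "X0s" maps to its midpoint X0+5 (so a weight in the
   60-kg band becomes 65 kg), and any code denoting an age below ten years
   maps to 5. Numeric literals pass through; anything unrecognized becomes
   missing with a warning rather than an error — spontaneous-report fields
   are dirty, and a row should not be lost to one bad code.
3. **BMI filtering.** BMI = weight / (height/100)² where both are present
   and positive. Records with BMI < 10 or > 100 kg/m² are removed as
   physiologically implausible data errors; the bounds are strict, so
   exactly 10 or 100 is retained, and records with missing BMI are kept
   (they still inform the non-BMI analyses; per-variable complete-case
   handling happens downstream).
4. **Merging.** Only suspect-role drug rows contribute exposures; cases
   with no suspect drug are excluded, as are table rows whose case id has
   no demographic record. History preferred terms are flagged into five
   groups (osteoporosis, cancer, arthritis, SLE, renal disorder) by
   case-insensitive exact-term membership in configurable SMQ-style term
   lists. MedDRA is licensed, so the shipped lists are small synthetic
   stand-ins with the real schema; production use plugs in licensed
   exports.

Record flow is conserved and reported: output count = input submissions −
dedup removals − no-suspect-drug removals − low-BMI removals − high-BMI
removals, checked on every run.

## Disproportionality screen

For each drug, each case counts once in a 2×2 table against the target
event. The reporting odds ratio is computed on cells to which 0.5 is added
unconditionally (Haldane–Anscombe); applying the correction to every
table — not only zero-cell tables — is deliberate, keeps the estimator
smooth across the zero boundary, and is the convention under which the
reference values reproduce exactly. The confidence interval is Woolf's
log-normal interval on the same corrected cells.

Statistical support is Fisher's exact test on the *raw* counts. The
hypergeometric pmf is evaluated via log-gamma over the whole support, so
margins in the millions are handled without underflow; the two-sided
p-value follows the "sum of probabilities ≤ observed" convention (with a
1e-7 relative guard for floating-point ties), and the right-tailed value
is P(A ≥ a). Any zero margin returns p = 1. A drug is screened as a signal
when ROR ≥ 1 **and** p ≤ 0.05, both inclusive. No multiplicity adjustment
is applied: the screen is descriptive triage, not confirmatory inference,
and feeds the volcano plot (−log₁₀ p against ln ROR, coloured by log₁₀ of
the drug's report count; the axis assignment is configurable since both
orientations are in circulation).

## Univariate comparisons and the logistic model

Continuous patient variables are compared between case and non-case
reports by the Wilcoxon rank-sum test (exact for small tie-free samples,
normal approximation otherwise), sex by Fisher's exact two-sided test, and
history flags by the right-sided exact test (enrichment is the only
direction of interest). Each variable uses its own complete cases.

The multivariable model is a maximum-likelihood logistic regression
(Newton iterations via statsmodels) on complete cases. Binary predictors
are effect-coded −1/+1; the odds ratio reported for a binary predictor is
the unexposed → exposed contrast exp(2b), which is invariant to the coding
choice (the package also supports 0/1 coding, and the test suite verifies
identical fitted probabilities with the slope ratio 2). Continuous
predictors (age, BMI) are untransformed and reported both per unit,
exp(b), and over the observed post-filter range, exp(b·(max − min)) — the
range form makes a small per-unit effect comparable with the binary
contrasts. Intervals are Wald. Complete separation is detected and
reported naming the offending predictor; the pipeline's auto-selection
(univariate-significant patient factors plus screened drugs with at least
5 exposed events, capped at 15) drops a separated predictor with a warning
and refits.

## Weibull time-to-onset

Onset is event date − administration start date + 1 (same-day onset is
day 1); pairs with the event before the start, or with either date
missing, are excluded. All observations are events — a spontaneous report
exists because the event happened — so the likelihood is uncensored;
right-censored fitting is out of scope.

The two-parameter Weibull MLE uses the profile likelihood: the shape β̂
solves the one-dimensional score equation by bracketed root finding
(log-sum-exp shifts keep the score finite at the extreme shapes visited
while bracketing), and the scale has the closed form α̂ = (mean tᵢ^β̂)^(1/β̂);
at β = 1 this reduces to the exponential MLE, the sample mean. The fit is
verified in tests against an independent zoom-grid maximizer and against
lifelines' Weibull fitter. Confidence intervals are Wald on (log α, log β)
from the finite-difference observed information — the log scale respects
positivity and gave 94–96% empirical coverage for β at n = 100 in
simulation. A fit requires at least five distinct durations.

Pattern classification follows the shape: β < 1 early failure (decreasing
hazard), β = 1 random, β > 1 wear-out (hazard rising with time on drug).
Because a point estimate above 1 with an interval straddling 1 is weak
evidence, the label and its CI support are reported separately:
`ci_supported` is true only when the interval excludes 1 on the pattern's
side. Strata are drug × indication; a case enters the osteoporosis or
cancer stratum according to its history flags (a case with both flags
contributes to both). Empirical medians and quartiles use the
linear-interpolation quantile convention. Default minimum stratum size in
the pipeline is 10.

## Synthetic generator

The generator emulates the rare-event regime of a large extract: the
target event near 0.1% of reports, decade-coded demographics, ~55%
missingness in height and weight (typical of such databases, and what
makes the complete-case logistic n much smaller than the screen n),
optional duplicated submissions, and per-drug Weibull onset times drawn as
the ceiling of continuous draws so the "+1 day" onset convention recovers
the drawn value exactly (the start date is back-dated from the event
date). The event indicator follows a logistic model, so every configured
drug carries an exact planted odds ratio and covariate effects are exact
log-odds. Default covariate effects use realistic magnitudes (female
ln 4.0, BMI 0.10 per kg/m², osteoporosis ln 2.5, SLE ln 1.9, arthritis
ln 1.3); the baseline logit default of −8.0 was set so that these effects
still yield ~0.1% marginal prevalence. Cases with no configured exposure
receive one effect-free filler suspect drug so every case has a suspect
drug.

What the generator does **not** emulate: reporting biases (notoriety,
channeling), within-case drug–covariate correlation (exposures are
independent of demographics, so the planted marginal and conditional odds
ratios coincide — real confounding is absent), Japanese/MedDRA-coded field
vocabularies, and non-independent cases. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to the biases of real spontaneous-report data.

## Validation design and problem sizes

The test suite checks, among others: exact reproduction of the reference
corrected RORs and Woolf bounds from printed-scale counts; agreement of
the exact-test implementation with exhaustive rational-arithmetic
enumeration over every 2×2 table with total ≤ 40; Weibull recovery over
100 planted strata of n = 100 (per-stratum fixed seeds, scale 300–3000
days, shape 0.8–3) with grid-search cross-checks, a median shape error
around 5%, and interval coverage inside [90%, 98%]; logistic coding
equivalence and 3-SE recovery at n = 50,000; and an end-to-end run of
200,000 synthetic reports in which the one drug planted at odds ratio 20
with 1% exposure is the only screened signal and its interval covers the
truth. Null-drug p-values are checked for *super*-uniformity (no excess of
small values) rather than two-sided uniformity: exact tests on cells with
expected counts below 1 are conservative and discrete, so their null
p-values sit stochastically above uniform by construction. These sizes
keep the whole suite in the low minutes on a single core while leaving the
statistical checks well-powered.
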