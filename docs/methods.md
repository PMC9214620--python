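# Methods

## Design of the screen

The package implements a medication-wide association study (MWAS) over a
delivery cohort. The unit of analysis is the delivery, not the patient: a
patient with two deliveries contributes two rows, and the logistic models
carry no clustering adjustment — the screen is a hypothesis-generating
device, not an inferential endpoint, and plain per-medication fits keep
its calls comparable across medications.

Three nested adjustment sets are screened. Model 1 is unadjusted; model 2
adds maternal age (linearly — no functional form beyond linearity is
assumed); model 3 adds binary indicators for ART-resulting pregnancy and
infertility diagnosis, the two strongest known confounders of multiple
birth available in coded data. Diagnosis-based adjustment is deliberately
coarse: many patients on fertility medication carry neither code, which
is precisely why the medication screen is informative.

## Outcome and covariate coding

* **Multiple birth (MB)**: an MB-list ICD code for the same patient dated
  exactly on the delivery date. Codes dated during the pregnancy are
  ignored because a multifetal-pregnancy code does not guarantee a
  multiple birth (fetal count can fall before delivery). "At the time of
  delivery" is operationalised as date equality with a configurable ± *k*
  day tolerance (default 0), since encounter-level linkage is not part of
  the data model.
* **ART / infertility**: any matching code dated within
  [delivery − 315 d, delivery], both ends inclusive. The 315-day lookback
  anchors on the *recorded* delivery date; an expected (clinical) delivery
  date is not in the data model, so the recorded date stands in for it.
* **Code matching**: exact string match, plus family-prefix match when a
  list entry ends in a dot (`O30.` matches `O30` and `O30.x`). Unknown
  code systems produce a warning and never match.

The shipped code lists are editable package defaults (plausible ICD-9-CM
and ICD-10 families); any site should substitute its own curated lists
via the `code_lists` CSV input.

## Exposure definition

Orders are mapped to ingredient-level medication ids by exact
case-insensitive name match against an annotation table in which brand
and generic names share one id; unmatched names are counted and dropped
(terminology normalisation is upstream of this package). A delivery is
exposed to an ingredient iff at least one order falls within
[delivery − 275 d, delivery − 215 d], both endpoints inclusive — the
window brackets conception and the early first trimester for a term
pregnancy, where fertility medications concentrate. Both-inclusive
endpoints are a documented choice (the window is stated in whole days
with no open/closed convention); they are config-overridable. Medications
prescribed to fewer than five *distinct patients* (not deliveries) inside
the window are dropped, and the retained count fixes the Bonferroni
family size before any model is fitted, so a downstream fit failure never
changes the multiplicity correction.

## Fitting and inference

The logistic fitter is Newton–Raphson / IRLS with the intercept included
in the design. Numerical choices:

* convergence when the largest coefficient update is below 1e-8, capped
  at 100 iterations; linear predictors are clipped at ±35 to keep the
  working weights finite;
* aliased columns (rank deficiency, e.g. a constant non-intercept
  column) are detected by a greedy left-to-right rank scan, dropped from
  the fit and reported as NaN, leaving the remaining coefficients exactly
  as in the reduced fit;
* standard errors come from the inverse observed information at the
  final iterate; intervals are Wald, exp(β ± 1.96·SE), with two-sided
  Wald P values — the large-sample GLM convention, using 1.96 rather
  than a t quantile;
* **separation**: when a coefficient's MLE runs off to ±∞ the deviance
  still stabilises, so the loop also stops once the deviance change is
  below 1e-12·(|deviance| + 0.1) *while* some coefficient exceeds 10 in
  magnitude; a coefficient is marked diverged when |β| > 30, or |β| > 10
  with an exploding (> 10) or undefined Wald SE. A medication is
  suppressed (no OR/CI/P, `converged = 0`) only when its *own exposure
  coefficient* diverges or the fit as a whole fails; a diverging nuisance
  covariate (e.g. an infertility stratum with zero events) leaves the
  exposure OR reportable, which matches how standard GLM software behaves
  on such data. No penalised (Firth-type) fallback is applied: a
  penalised OR would silently differ from the maximum-likelihood OR the
  screen advertises.

Bonferroni-adjusted P is min(1, m·P) with m the retained medication
count; the Bonferroni call set is a subset of the nominal call set by
construction, and the reporting layer refuses to render artifacts that
violate this.

## Validation against the gold standard

Significance calls (nominal or Bonferroni mode) are scored against the
fertility-medication list as truth. Every scored medication lands in
exactly one confusion-matrix cell. Metrics with a zero denominator are
reported as undefined, never as 0. Full precision is kept internally;
presentation rounds to 2 decimals, and the presented F1 is recomputed
from the *rounded* precision and sensitivity — the convention of
published performance tables in this setting (at full precision the
reference nominal row's F1 is 0.537; from rounded components it is 0.53).

## Synthetic data generator

The generator emulates a large single-center delivery cohort: 63,334
deliveries, maternal age truncated-normal 29.5 (SD 6.1) on [12, 55]
years, ART prevalence 0.39%, infertility 0.08%, baseline MB logit set to
logit(0.0247), and a per-medication exposure prevalence of
1 − (1 − 0.0296)^(1/123) ≈ 2.44 × 10⁻⁴ so that *any*-exposure is 2.96%
under independent draws. Exposure effects are planted on the log-odds
scale; the study-scale scenario (`paper_scale_config`) plants log 6 on
each of the 15 gold-standard fertility ingredients — the effect size is a
free parameter chosen once as a realistic fertility-medication effect.
Default nuisance effects are β_ART = log 8 and β_inf = log 2 with age
effect 0, so the configured baseline equals the marginal MB rate to
within rounding.

Dates are day-granularity ISO-8601; all windows are integer-day
arithmetic relative to the delivery date. Exposure draws are independent
across medications by default; a correlated-block hook
(`exposure_blocks` + `block_correlation`) exists for stress tests only.
Decoy emission adds records that must be invisible downstream: MB codes
dated 30–200 days before delivery on non-MB deliveries, ART/infertility
codes 316–500 days before delivery, and orders at exactly 214/276 days —
one day outside each window endpoint.

What the generator does *not* emulate: realistic ICD code frequency
distributions, co-prescription structure, dose/route/duration, multiple
deliveries per patient with realistic spacing (a uniform-spacing flag
exists but defaults off), or missing/incomplete medication capture.
Passing tests therefore demonstrate the pipeline's correctness and
calibration under the stated generative model, not robustness to real
EHR messiness.

## Simulation scales used by the test suite

Chosen as the package's own verification design:

* **Margin calibration**: one null cohort of 50,000 deliveries; the
  empirical MB rate must sit within 3 binomial SDs of the configured
  2.47%.
* **Type-I error**: 20 all-null cohorts of 20,000 deliveries × 123
  medications at exposure prevalence 0.05 (≈ 1,000 exposed per
  medication, enough events for Wald inference to be exercised
  meaningfully); the pooled nominal rejection fraction must sit within 3
  binomial SDs of α = 0.05.
* **Parameter recovery**: 100 cohorts of 20,000 deliveries with a
  planted OR of 6 at exposure prevalence 0.02 (≈ 400 exposed, ≈ 50
  events); the 95% Wald CI must cover 6 in ≥ 93% of replicates.
* **Oracle equivalence**: 50 random datasets compared against an
  established GLM implementation at 1e-6 absolute agreement on
  coefficients and SEs; 1,000 random 2×2 tables checked against the
  closed-form cross-product odds ratio.

## Known limitations

* Exposure is prescription-based: no dispensing or adherence signal, and
  no within-window timing — an order at day 275 and one at day 215 are
  identical exposures.
* The lookback and window anchor on the recorded delivery date, so
  preterm deliveries shift the true conceptional window relative to the
  fixed 275–215-day band.
* Repeat deliveries of one patient are treated as independent.
* Bonferroni is the only multiplicity control offered; it is
  conservative for correlated exposures.
* The gold standard treats every fertility-treatment ingredient as a
  true positive, so the reported precision conflates screen errors with
  gold-standard incompleteness.
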