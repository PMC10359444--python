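# Methods

## Scope and model

The package computes single-antecedent association rules between binary
risk-factor states and a binary 5-year kidney outcome in diabetic
cohorts, within clinically defined strata. The two mined directions are
*absence → stable* and *presence → worsening*; for each cell the package
reports the four exact counts (n_all, n_antecedent, n_joint,
n_consequent), confidence = n_joint / n_antecedent, lift =
confidence / (n_consequent / n_all), and the significance call
lift > 1.0 (strict). No multivariable adjustment is attempted — the
method's selling point is transparency, and its blind spot (confounding)
is inherited deliberately. Multi-antecedent itemset mining is replaced by
stratification on known clinical status: CKD risk category, diabetic
retinopathy, and the 2-year eGFR change.

Undefined cells are first-class: an empty antecedent yields NaN
confidence (0/0 is not evidence), and undefined cells are never
significant. Subjects missing a factor's value are excluded from that
factor's four counts only (per-factor complete case); listwise deletion
was the alternative and was rejected because it would let an unrelated
factor's missingness distort another factor's denominators. As a result
n_all may differ between factors within one stratum, which the output
format records per cell.

## Kidney metrics

eGFR comes from the Japanese three-variable creatinine equation
(194 × Cr^−1.094 × age^−0.287, × 0.739 for women), in mL/min/1.73 m².
Worsening is a ≥ 30 % eGFR decrease from baseline at **any single**
in-window follow-up (no confirmation visit required); the boundary value
−30 % exactly counts as worsening. eGFR is carried at full float
precision with no intermediate rounding, so the boundary is not subject
to rounding artifacts. Worker-type cohorts additionally count
ESKD/dialysis/transplant events inside the window; events after the
window are ignored. The 2-year change uses the measured follow-up nearest
baseline + 2 years within ± 1 year (annual examinations make exact
2-year visits unlikely); ties resolve toward the earlier visit; bins are
≥ 0 %, [−30 %, 0), < −30 %. A subject in the < −30 % bin has, by
construction, already met the 5-year outcome — the tests assert this
structural fact.

## Eligibility

Baseline is the oldest creatinine-bearing visit with at least one later
visit and a span of ≥ `followup_years` (default 5) to the subject's last
visit. Eligibility additionally requires diabetes at baseline (HbA1c
≥ 6.5 %, fasting glucose ≥ 7.0 mmol/L, or current diabetes treatment;
missing criteria count as not met, and when all three are missing at
baseline the earliest earlier visit carrying any criterion is consulted)
and ≥ 1 measured follow-up within (baseline, baseline + followup_years].
Whether diabetes must hold at baseline or at any visit is a genuinely
open choice; baseline anchoring was selected because every other factor
is baseline-anchored, and the alternative is one flag away in
`is_diabetic`. Exclusion reasons are attributed first-failing-rule-wins
in the order not diabetic → no baseline eGFR → insufficient follow-up;
the order affects attribution only, never the final count (tested).

## Binarization

Continuous factors are dichotomized at the upper or lower 20 % of the
baseline distribution **by sex**, computed within the analysis cohort
before stratification; 10 % is the sensitivity setting. The percentile
estimator is linear interpolation between order statistics (numpy
default) — the estimator is configurable in principle but this default is
documented and fixed for determinism. Presence requires **strict**
exceedance; a value exactly at the threshold is absent. This makes the
degenerate constant-factor case flag nobody and keeps the rule
quote-consistent with "above the 80th percentile". Low tails are risky
for eGFR, hemoglobin (anemia) and HDL-C; high tails for the remaining
continuous factors. Dipstick proteinuria ≥ 1+ is a categorical risk
(negative/trace is none). Retinopathy and the 2-year change are carried
as stratifiers, not rule factors, by default; retinopathy can be promoted
to a rule factor by giving it a non-stratifier spec.

## CKD staging

GFR grades follow the standard lower-inclusive bounds (≥ 90, 60–89,
45–59, 30–44, 15–29, < 15). The risk-category grid replaces albuminuria
with the dichotomized dipstick: negative/trace follows the A1 column
(G1/G2 low, G3a moderate, G3b high, G4/G5 very high) and ≥ 1+ the A2
column (G1/G2 moderate, G3a high, G3b+ very high). Whether ≥ 1+ should
behave like A2 or A3 for preserved GFR cannot be settled from dipstick
semantics alone (1+ ≈ 30 mg/dL sits near the A2/A3 boundary); A2 was
chosen as the conservative reading and the grid is an explicit mapping
that callers can override. The four categories collapse to
low/moderate vs high/very-high for the retinopathy-crossed schemes.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not kidney physiology:

- **Marginals.** Each analyte is truncated-normal with cohort-specific
  mean/SD defaults typical of an older community screening population
  (e.g. HbA1c 7.4 ± 1.3 %, eGFR 75.0 ± 18.3) and of a younger, 96 %-male
  working population (HbA1c 7.3 ± 1.4, eGFR 80.1 ± 16.1). Ages are
  66.7 ± 7.7 vs 47.8 ± 5.5 years; dipstick ≥ 1+ prevalence 11.6 % vs
  29.1 %.
- **Latent risk states.** Each subject first draws a Bernoulli risk state
  per factor (prevalence = the intended tail fraction, default 0.20);
  the analyte is then sampled from the corresponding tail or body of its
  marginal. Downstream percentile binarization therefore re-identifies
  the latent state with accuracy > 0.9 (tested), which is what makes
  parameter-recovery tests possible.
- **Outcome.** P(worsening) = `worsening_base_rate ×
  Π effect_map[f]` over present factors, capped at 1. The default
  effect map gives glycemic control, proteinuria, anemia, low eGFR,
  blood pressure and adiposity modest relative risks (1.3–2.5) and
  leaves the rest null; the profile constructors calibrate the base rate
  so the marginal 5-year worsening rate lands at ≈ 4.8 % (general) /
  5.1 % (worker), the realistic order for this outcome. The closed-form
  marginal and conditional probabilities are exposed
  (`analytic_worsening_probability`, brute-force enumeration over factor
  states) and serve as the oracle in recovery tests.
- **Trajectories.** Worsening subjects decline linearly in relative eGFR
  so the −30 % boundary is crossed at a uniformly random whole year in
  [1, 5]; stable subjects get i.i.d. ± 3 % multiplicative noise (which
  cannot reach −30 % even compounded with ageing). Visit creatinine is
  back-computed from the target eGFR through the Japanese equation, so
  the pipeline's recomputed eGFR reproduces the designed trajectory
  exactly. Follow-up analytes wobble by ± 2 % around baseline.
- **Diabetes closure.** Subjects below both lab criteria are marked as
  treated, so the simulated population is all-diabetic by construction —
  the eligibility filter is exercised by dedicated fixtures instead.

What the generator does **not** emulate: physiological coupling between
analytes (beyond the factor → outcome links), treatment effects,
mortality or censoring, progressive proteinuria, and the positive skew of
GGT/triglycerides — their positive-truncated normals have realized means
above the nominal parameter, so marginal-recovery checks use lightly
truncated analytes. Passing tests therefore certify the analysis
machinery, not clinical realism.

## Numerical and reproducibility choices

All randomness flows through one `numpy.random.Generator` per simulated
cohort; equal seeds give byte-identical CSVs (tested at byte level
through the full pipeline). Truncated normals are sampled by inverse-CDF
so no rejection loop perturbs the stream. Rule results are emitted in a
fixed (scheme, stratum, factor, rule) order with the complete
cross-product retained, empty strata included. The pipeline removes
partial outputs when a stage fails and writes a manifest (config hash,
seed, versions) from which a run can be reproduced.

Problem sizes in the test suite were chosen to make the statistical
checks decisive at interactive runtimes: 200 brute-force oracle tables of
≤ 20 rows, parameter recovery at n = 20 000 (3 binomial SEs), null
calibration over 200 replicate cohorts of n = 2 000, and threshold
behaviour at n = 1 000 per sex. The acceptance script uses n = 5 000 per
cohort.

## Known limitations

- Lift is reported without an uncertainty statement, mirroring the
  lift > 1 significance convention; an optional percentile bootstrap for
  confidence exists (`bootstrap_confidence_interval`) but is off by
  default and is an extension, not part of the core method.
- Sparse strata (very-high risk, slope-crossed cells) produce unstable
  or undefined confidences; the output keeps them visible rather than
  suppressing them.
- Uniform percentile thresholds are not clinically anchored cut-offs;
  that is a property of the method, not of this implementation.
- The eligibility cascade assumes one record stream per subject; record
  linkage and deduplication are out of scope.
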