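# Methods

## Scope and model

adipoquant implements a complete analysis chain for asking which field
method of estimating adolescent body fat best predicts cardiometabolic
risk:

1. twelve percent-body-fat (%BF) estimators — ten anthropometric
   prediction equations (`EQ1`–`EQ10`) and two bioimpedance routes
   (`BIA1`, `BIA2`);
2. derived fasting biomarkers (Friedewald LDL, HOMA-IR, lipid ratios, BMI)
   and fixed-cutoff clinical risk flags;
3. a screen → adjusted-regression → ranking pipeline that scores each %BF
   method by the number of risk factors it predicts;
4. a calibrated synthetic-cohort generator so the whole chain can be
   exercised, and its operating characteristics measured, without any
   subject-level data.

## The body-fat battery

Three estimator families appear.

**Densitometric** (`EQ1`, `EQ5`). Whole-body density D (g/mL) is a linear
model in log10 of a four-skinfold sum (biceps + triceps + suprailiac +
subscapular, mm); %BF follows from the Siri two-compartment conversion
`%BF = (4.95/D − 4.50) × 100` (`EQ1`) or an age-adjusted Siri-like form
(`EQ5`). Every `log` in the published equations is base 10; this is
centralised in one helper. Density is carried in g/mL: the published
coefficients only make sense at that scale even where a legend says g/L.

`EQ1` selects coefficients by completed years of age: 15–16 uses the
adolescent coefficients, 17–18 the adult ones; ages outside 15–18 raise an
unsupported-age error.

`EQ5`'s published rendering drops closing brackets; the implementation uses
the reconstructed reading

    male:   %BF = (562 − 4.2(A−2))/D − (525 − 4.7(A−2))
            D = (1.1315 + 0.0018(A−2)) − (0.0719 − 0.0006(A−2))·log10(Σ4)
    female: %BF = (553 − 7.3(A−10))/D − (514 − 8.0(A−10))
            D = (1.1350 + 0.0031(A−10)) − (0.0719 − 0.0003(A−2))·log10(Σ4)

The female density multiplier mixes an (A−2) term into an otherwise
(A−10)-based form; it is implemented exactly as printed, with
`female_consistent_age_term=True` switching to the (A−10)-consistent
variant. Both readings are exposed because the published text cannot
settle the question.

**Direct %BF** (`EQ2`, `EQ3`, `EQ4`, `EQ7`, `EQ8`, `EQ10`). Linear or
quadratic forms in skinfold sums, BMI (computed internally, kg/m²) or
weight. `EQ4` switches at a triceps+subscapular sum of 35 mm; the
published footnotes say "<35" and ">35", which orphans exactly 35 mm —
resolved to the quadratic branch. Its male low-sum intercept varies with
race and maturation; the study's "non-white" grouping maps onto the
black-coefficient forms here and in `EQ10` (configurable). `EQ8` codes sex
masculine = 1, feminine = 0 and switches child/adult coefficients at
completed age 16. Decimal age is used wherever age enters arithmetically;
completed years select categorical branches.

**Fat-free mass** (`EQ6`, `EQ9`, `BIA1`). FFM (kg) is predicted from
anthropometry and the impedance index Ht²/R (cm²/Ω); then, exactly,
`fat_mass = weight − FFM` and `%BF = 100·fat_mass/weight`. `EQ6`'s male
form needs the arm muscle circumference, derived as
`brachial_perimeter − π·triceps/10` (cm). `BIA1` models a horizontal
tetra-polar device whose internal equation is proprietary: the resistance
reading is fed through a configurable FFM equation (default `EQ9`, the
only published resistance equation covering both sexes; `EQ6` is the
alternative binding). `BIA2` (vertical eight-electrode device) is a direct
%BF input column for the same reason.

Out-of-range results (%BF < 0 or ≥ 100) are returned with an
`out_of_range` flag, never clamped, so downstream reports can show them;
clamping is left to callers. The excess-fat classification flags %BF at or
above 20% (male) / 25% (female), boundary inclusive — the "risk of
overweight and above" pooling; the thresholds are configurable because the
source classification table is not reproduced in the text.

A battery call returns estimates in canonical method order plus structured
skips naming the missing measurement for any method that could not run;
`strict=True` turns skips into errors.

## Biomarkers and risk flags

Derived quantities are pure functions of the fasting measurements:
Friedewald LDL `TC − HDL − TG/5` (invalid at TG ≥ 400 mg/dL, which raises),
HOMA-IR `insulin (µU/mL) × glucose (mg/dL) / 405` (the mass-unit HOMA1
convention — the printed unit "µU/dL" is treated as the standard µU/mL,
without which the index would be two orders of magnitude off its printed
group means), the TC/HDL and LDL/HDL ratios, and BMI.

Risk flags follow fixed cutoffs with their printed comparators: TC ≥ 150,
LDL ≥ 100, HDL ≤ 45, TG ≥ 100 (mg/dL); fasting glucose ≥ 100 mg/dL (ADA
convention, configurable — the guideline value is not printed in the
source); hyperinsulinemia ≥ 15 µU/mL (configurable, same reason); HOMA-IR
≥ 3.16; uric acid strictly above 7.0 (boys) / 6.0 (girls) mg/dL with a
pooled > 7 option; blood pressure ≥ 120 systolic or ≥ 80 diastolic mmHg.
`risk_count` counts true component flags and `any_risk` is their OR.

The cross-sectional sample-size operation computes
`n0 = z²·p(1−p)/d²` with the two-sided normal quantile, applies the
finite-population correction `n0 / (1 + (n0−1)/N)` and rounds up; at the
study's inputs (N = 5010, p = 0.5, d = 0.07, 95%) it returns 189.

Report-style rounding is decimal half-up at one decimal; full precision is
kept internally.

## Association pipeline

The statistical procedure mirrors a standard epidemiological screen:

* **Distribution checks** use the Lilliefors-corrected Kolmogorov–Smirnov
  test (parameters estimated from the data). The uncorrected KS test with
  estimated parameters is badly anti-conservative and would never route
  skewed variables to the nonparametric comparison.
* **Group comparisons**: equal-variance Student's t when the distribution
  check passes, Mann–Whitney U otherwise.
* **Log transform**: TG, insulin, HOMA-IR, LDL, TC, LDL/HDL and TC/HDL are
  analysed as log10 values; regression slopes for these outcomes are on
  the log10 scale.
* **Bivariate screen**: OLS of each outcome (analysis scale) on each
  method's %BF; cells with P < 0.20 (strict) are admitted.
* **Adjusted model**: OLS with covariates — sex (masculine = 1), and in
  the eutrophic group an "excess fat despite normal BMI" indicator
  (classify_excess_fat applied to a configurable reference method, default
  `EQ5`; the source does not pin the method down). Shapiro–Wilk on the
  residuals gates reporting (P > 0.05 required; failing cells mirror the
  dashes of the source tables). The White test probes heteroskedasticity;
  when it rejects at 5% the %BF standard error and P-value are recomputed
  under a small-sample robust covariance (HC3 default; HC1/HC2
  configurable). The variance inflation factor over non-intercept
  regressors monitors collinearity; rank-deficient designs raise an error
  naming the collinear columns.
* **Ranking**: methods are ordered by the number of outcomes with an
  admitted, assumption-clean, adjusted P < 0.05 association; ties break by
  mean adjusted R² over the significant cells, then canonical method order
  (purely for determinism).

No multiplicity correction is applied by default, matching the source
procedure; a Benjamini–Hochberg option exists (`bh_correction=True`).

A noteworthy interaction, measured during calibration: the eutrophic-group
false-negative indicator is a coarsening of the reference method's own %BF,
so it is maximally collinear with that method's regressor and drains its
partial significance specifically. This is a property of the adjustment,
not a defect; the operating-characteristic experiments therefore use the
sex (and, for pooled cohorts, group) adjustment.

## Synthetic cohorts

The generator emulates the two-group study structure: a eutrophic group
(n = 140) and an overweight group (n = 70), 52.4% female, 61.4% non-white,
with per-group mean/SD/min–max targets for age, weight, height and the
fasting biomarkers taken from the published group table.

**Marginals.** Right-skewed variables (TG, insulin, LDL) are lognormal,
the rest Gaussian, all truncated to the printed min–max ranges. For each
marginal the parent (µ, σ) is calibrated by root finding so the
*truncated* distribution's mean and SD equal the targets exactly (closed
forms exist for both families); naive truncation of a parent with the
target moments would bias heavily one-side-truncated variables by several
percent. Sampling goes through a Gaussian copula and inverse-CDF
transforms, which carries the biomarker correlation matrix (symmetric PSD,
defaults encode modest lipid/insulin/pressure dependence) and keeps every
draw a pure function of the seeded generator stream — identical seeds give
byte-identical cohorts.

**Identities by construction.** LDL is drawn from its own published
moments and total cholesterol is assembled as `LDL + HDL + TG/5` — the
generative direction of the Friedewald identity and the physiological one
(TC is the sum of its fractions). HOMA-IR and the ratios are always
computed from the drawn measurements. Re-deriving every derived field from
the stored measurements reproduces the stored values exactly.

**Anthropometry.** A latent adiposity factor drives all six skinfolds
through site-specific loadings with site-specific lognormal noise
(inter-site correlation ≈ 0.6–0.8, the realistic range), a female factor
(×1.35) and an overweight-group factor (×1.8); weight shares the factor
through the copula (ρ = 0.55). Resistance follows the physics of a
tetra-polar measurement, `R ≈ 0.61·Ht²/(FFM − 0.25·Wt − 1.31)` for a
latent FFM consistent with the skinfold model, with ~6% multiplicative
device noise; the direct vertical-device %BF is the impedance estimate
plus 2-point Gaussian device noise. These choices make the twelve %BF
estimates correlate strongly but imperfectly (skinfold family ≈ 0.9–0.98,
impedance vs skinfold ≈ 0.8, BMI/weight-based ≈ 0.5–0.7) and give a wide
per-method spread of excess-fat frequency in the eutrophic group, the
method disagreement the analysis feeds on.

**Planted effects.** A `(method, outcome) → PlantedEffect(slope, noise_sd,
scale)` map injects signal: the planted outcome is regenerated as
`target_mean + slope·(%BF − mean %BF) + noise` on the linear scale, or the
same linear model on log10(outcome) (`scale='log10'`) — the scale on which
the skewed outcomes are analysed, which also keeps them positive. Planted
values are clipped to the printed observed range, preserving Friedewald
validity (TG < 400). With zero noise the screen recovers the slope exactly
with r² = 1 on the corresponding analysis scale. `plant_null` zeroes all
slopes. Sex differences in height and weight are not modelled (the
published moments are group-pooled), and pubertal dynamics and duplicate
measurement protocols are out of scope: passing tests show the pipeline
behaves correctly under the study's documented first-order structure, not
that it reproduces unpublished higher-order structure of the real cohort.

## Operating-characteristic experiments

`adipoquant.experiments` packages seeded experiments used by the tests and
the acceptance script (problem sizes are the package's own defaults):

* **Null calibration** (1,000 simulated 12 × 12 grids at n = 140): the
  screen's type-I rate at its 0.20 threshold (≈ 20%), the adjusted model's
  type-I rate at 0.05 computed on every cell (≈ 5%), and the pipeline's
  composed significant-cell rate (screen-admitted ∧ normality gate ∧
  adjusted P < 0.05). The composed rate runs ≈ 3.5%, below the adjusted
  model's nominal level, for two faithful reasons: the sex adjustment
  erases part of the spurious bivariate admissions, and the ratio and
  uric-acid outcomes often fail the residual-normality gate — exactly the
  rows dashed in the source's own multivariate tables.
* **Planted-signal attribution** (100 pooled two-group cohorts, n = 210):
  `EQ5`'s %BF drives TG, insulin (hence HOMA-IR) and DBP at per-outcome
  R² ≈ 0.45, the upper end of the published coefficients; the grid over
  the signal-bearing outcomes, adjusted for sex and group, should rank
  `EQ5` first. The measured first-place fraction is ≈ 0.8–0.9 and is
  structurally capped below 0.9: even with its residuals exactly normal,
  the source method must survive four independent Shapiro–Wilk gates with
  5% false-alarm probability each (0.95⁴ ≈ 0.815 as the dominant term; the
  remainder comes from competitors sharing a failed gate), and any
  near-duplicate competitor (the equations sharing the same four-fold sum
  correlate at ρ ≈ 0.97 with `EQ5` by construction) that survives its own
  gates ties or out-counts it. Ranking on the full 12-outcome grid is
  noisier still — chance significant cells among the eight null outcomes
  let the maximum of eleven competitors out-count the source roughly half
  the time at any effect size. This cap is a property of count-based
  ranking with per-cell assumption gates and no multiplicity correction,
  worth knowing before trusting a single-dataset "best method" call.
* **Slope recovery** (500 replicates, n = 140, planted slope 0.006 at
  r² ≈ 0.06): the OLS slope is recovered with well under 10% bias.
* **White-test power** (200 replicates, n = 140): error SD proportional to
  %BF is detected ≈ 99% of the time, switching the fit to robust errors;
  on homoskedastic data the robust switch stays off ≈ 95–98%.
* **Battery–oracle agreement** (1,000 random subjects): every method
  matches an independently written single-expression evaluator to better
  than 1e−9 %BF.

## Numerical and interface choices

* Subject CSV: UTF-8, comma-separated, "." decimals (a decimal-comma
  switch exists for Brazilian-style sources); empty cells are missing
  values; a YAML column mapping renames headers. Row-level validation
  failures are collected with row numbers, never silently dropped.
* Thresholds must satisfy 0 < α < screen < 1; configuration is validated
  before any compute. Reports carry a provenance block (package version,
  seed, config SHA-256 excluding output paths).
* Moment-target infeasibility (an SD impossible inside the truncation
  range) raises a spec error at calibration time.
* The grid never aborts on a per-cell failure; failed cells carry
  machine-readable reasons.

## Known limitations

* The proprietary equations inside the two BIA devices are unpublished;
  both are modelled (configurable FFM binding; direct input column), so
  `BIA1` duplicates its bound equation exactly.
* The generator makes no claim to reproduce the study's 76.7% any-risk
  prevalence: that depends on joint tail dependence the published moments
  do not identify. The tests assert the prevalence responds monotonically
  to biomarker dispersion instead.
* Real regression coefficients of the source tables are not reproducible
  without the undeposited raw data; the pipeline is validated structurally
  on synthetic cohorts.
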