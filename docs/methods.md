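# Methods

## Scope and model

The package operationalises a cross-sectional method-comparison study of
skeletal-muscle biomarkers in older oncology outpatients.  Three measurement
families feed a common per-subject record (canonical units: height m, weight
kg, thicknesses mm, areas cm², radiodensity HU, impedance Ω, phase angle °,
grip kg; sex coded female = 0 / male = 1):

1. **CT at L3** — measured skeletal muscle area (L3-SMA) and mean
   radiodensity (L3-SMD, segmented in the −29…+150 HU window).  Derived:
   SMI-CT = SMA/H², SMG = SMI·SMD, Shen MM = (0.166·SMA + 2.142)·1.06,
   Mourtzakis FFM = 0.30·SMA + 6.06, and SMI-Shen = Shen MM/H².
2. **BIA** — raw R_z, X_c, Z, θ.  Derived: Janssen
   MM = 5.102 + 0.401·(H²/R) + 3.825·S − 0.071·A (H in **cm**), Kanellakis
   FFM (H in **m**), Kotler FFM (H in **cm**, power-law in H and Z).
   Device-proprietary Talluri MM/FFM values are accepted as optional
   pre-computed columns and never computed here.
3. **US** — RF-MT, Quad-MT (mm), RF-CSA (cm²).  Derived: the USVALID
   equation SMA = −54.0 + 21.0·S + 0.4·W + 0.6·H + 15.0·Q (H, Q in cm) and
   a refitted model with the same predictors obtained by OLS
   (`fit_sma_regression`), reported with adjusted R².

Unit adapters live inside each equation so the conversion wiring is testable
in isolation; a guard test asserts that feeding Kanellakis centimetres
instead of metres shifts the output by more than 10 kg on typical inputs.

Notes on sources: the printed Kotler equation is a single formula although
its original publication is sex-specific; it is implemented exactly as
printed.  "SMI-Shen" is interpreted as Shen whole-body MM divided by height
squared.  The Janssen height unit is not annotated in the source table; cm
is adopted because it is what the original equation uses and the only choice
producing whole-body masses in the observed 14–37 kg range.

## Diagnostic rules

A `CutoffSet` is a list of strata (optional sex, half-open BMI and age
ranges) each carrying one threshold; the engine selects the first matching
stratum and flags *strictly below* as abnormal, so boundary values are
normal.  Covariates outside every stratum raise an error rather than
defaulting.  Shipped sets: Dolan SMI-CT (sex × BMI < / ≥ 25), Dolan SMD
myosteatosis (BMI-keyed), Masanés and EWGSOP2 SMI-Janssen (sex-keyed), and
DRECO RF-MT / RF-CSA (sex-keyed; the male RF-MT threshold is printed below
the female one in the source and is shipped as printed).  A Van Vugt-style
template ships with empty rules for the user to populate from its external
source.

Dynapenia is grip strength strictly below an age/sex normative 10th
percentile.  The published normative centiles are not redistributable, so
the default table (`synthetic_grip_p10.yaml`) is synthetic — plausible,
age-declining, sex-separated values — and is replaceable via
`load_grip_table(path)`.  Sarcopenia is the conjunction atrophy ∧ dynapenia.

GLIM severity is the worst of two phenotypic criteria (etiologic criterion
assumed met for an active-oncology population): involuntary weight loss
(moderate > 5 % within 6 months or > 10 % beyond; severe > 10 % within 6
months or > 20 % beyond; voluntary loss ignored) and low BMI (moderate
< 20 kg/m² under age 70 or < 22 at 70+; severe < 18.5 / < 20).  Exactly age
70 is assigned to the older band.  Obesity is BMI ≥ 30 kg/m² — the source
text prints "≥ 20.0 kg/m²" at one point, which contradicts its own obesity
grade counts and is treated as a typo.  Stratified reporting dichotomises
age at 70 by default (configurable); 65 appears once in the source's
statistical-methods text and is treated as an inconsistency, not adopted.

## Agreement statistics

Implemented in `musclecompare.agreement` (not delegated to a statistics
package, because they are the package's verifiable core):

* **Bland–Altman** — differences d = reference − index, so positive bias
  means the index method underestimates (this sign convention is forced by
  the reporting pattern "index underestimated, positive bias" when the
  reference mean exceeds the index mean).  bias = mean(d) (identical to the
  difference of group means — the identity that lets printed group means
  validate printed biases), SD with n−1, LoA = bias ± 1.96·SD, a least-squares
  regression of d on pairwise means for dose-dependent bias (slope = 0,
  p = 1 for degenerate zero-variance input), and the count outside the LoA.
* **Lin's CCC** — population (1/n) moments per the original concordance
  definition; 95 % CI by Fisher z-transform with Lin's asymptotic variance;
  degenerate |ρ_c| = 1 collapses the CI to a point.  Bands: > 0.99 near
  perfect, 0.95–0.99 substantial, 0.90–0.95 moderate, < 0.90 poor.
* **Cohen's kappa** — unweighted, from the k×k contingency table, with the
  large-sample normal test using the null standard error from the marginal
  proportions; undefined when both raters are constant and identical.
* **Location tests** — Shapiro–Wilk gate at α = 0.05.  Paired: paired t if
  the differences pass, else Wilcoxon signed-rank with zeros dropped
  (Wilcoxon's original convention; all-zero differences return p = 1).
  Unpaired: two-sample t if both groups pass the gate **and** Levene's test
  at 0.05 finds homoscedasticity, else Mann–Whitney.  The rank-sum test for
  independent groups is a deliberate correction — a signed-rank test is
  undefined for unpaired groups of unequal size.

Correlation matrices are pairwise-complete and expose both Pearson (default)
and Spearman, since both conventions appear in this literature.  No
multiple-testing correction is applied anywhere, matching standard practice
for descriptive agreement batteries of this kind.

## Synthetic cohort generator

No raw study data are available, so `musclecompare.cohort` generates
cohorts with the *statistical structure the analysis assumes*; it makes no
claim to be a model of any real cohort beyond its calibration targets.

* Demographics: female fraction 0.481; age = 50 + Gamma(k = 3, θ = 5.5)
  truncated to [50, 90] (median ≈ 65, roughly a third aged 70+); height
  Normal per sex (F 1.58 ± 0.06 m, M 1.705 ± 0.06 m); BMI Normal(27.3, 4.3)
  clipped to [16, 48] (median ≈ 27, ≈ 26 % obesity); weight = BMI·H².
* One latent muscularity factor M ~ Normal(latent_mean, 1) is shared by all
  muscle channels.  Each channel is linear in (sex, M, age − 65,
  BMI − 27.3) plus Gaussian noise, clipped to its physiological floor:
  L3-SMA (female intercept 103.4, sex effect +41.8, loading 16), R_z
  (loading −35, i.e. resistance falls with muscularity), θ (falls with
  age), SMD (falls with age and adiposity, clipped to the segmentation
  window), RF-MT/Quad-MT/RF-CSA and HGS (rise with M, HGS falls with age).
  Coefficients were derived in closed form from target stratum means,
  standard deviations and correlations (e.g. corr(R_z, L3-SMA) ≈ −0.65,
  corr(θ, HGS) ≈ +0.5) by variance bookkeeping.
* X_c = R_z·tan(θ) and Z = √(R_z² + X_c²) keep the raw BIA quantities
  internally consistent.
* `make_paired_channel` adds source + bias + Normal(0, σ) columns for
  parameter-recovery tests of the agreement battery.
* Optional uniform-at-random per-channel missingness; the real mechanism of
  missingness in clinical cohorts is not modelled.
* Generation is a deterministic function of (spec, seed).

What passing tests therefore show: the pipeline's equations, rules and
statistics are correct on data with realistic marginals and a realistic
correlation skeleton.  What they do not show: behaviour under real-world
artifacts (device error, catheters/ostomies, fluid overload, informative
missingness, non-Gaussian channel noise), which the single-factor Gaussian
design does not emulate.

## Numerical choices and problem sizes

Computation is at full double precision; printed-precision rounding happens
only at the reporting edge (biomarkers 1 decimal, correlations/CCC/kappa 3,
p-values in scientific notation below 0.001).  Default analysis cohorts use
n = 156 (the natural size for this design); distribution-level checks use
n = 5 000–10 000 and the CCC closed-form check uses 10⁵ draws, sizes at
which Monte-Carlo error is comfortably inside the asserted tolerances while
the whole suite stays fast.  The type-I-error calibration uses 2 000 null
replicates at n = 30 per group.

## Known limitations

* The Van Vugt-style cut-off table and the published grip centiles must be
  supplied by the user; the shipped grip table is synthetic.
* The refitted US→SMA coefficients on a synthetic cohort differ from any
  real cohort's coefficients; only the noiseless/noisy recovery properties
  are asserted.
* CCC confidence intervals rely on the asymptotic normal theory and are
  approximate below n ≈ 30.
* No mixed-effects or repeated-measures extensions, no imputation, no image
  processing: areas, densities and thicknesses enter as numbers.
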