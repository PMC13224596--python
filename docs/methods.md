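# Methods

This note documents the models implemented in `dietkidney`, the design
choices taken where the analysis recipe leaves room, and what the
synthetic-data experiments do and do not demonstrate.

## Cohort preparation

**eGFR.** The outcome is the race-free CKD-EPI 2021 creatinine equation.
Constants (level 142, κ = 0.7/0.9, α = −0.241/−0.302, high-range exponent
−1.200, age factor 0.9938, female multiplier 1.012) live in `EGFRParams`
and can be swapped. The function is continuous at Scr = κ and strictly
decreasing in creatinine and age; `invert_egfr` solves the unique inverse
analytically, which the synthetic generator uses to back-solve creatinine
from a planted eGFR.

**BMR.** No specific basal-metabolic-rate equation is mandated by the
analysis design, so the default is Schofield's weight-based age-sex-band
formula (kcal/day), standard in European FFQ plausibility screening. Band
edges are [10, 18), [18, 30], (30, 60), [60, ∞); the equation name is a
config switch so a height-based alternative can be added without touching
the cascade.

**Exclusion cascade** (fixed order, per-step counts reported so any
re-ordering is visible): (1) self-reported kidney disease, hypertension
or diabetes, or a corresponding medication; (2) > 80% missing biomarker
values; (3) > 20% missing FFQ items (strict); (4) TEI/BMR ratio outside
the closed [0.5th, 99.5th] percentile interval computed on the post-(3)
sample, with linear-interpolation quantiles (the common statistical
default). Note that with continuous data and interpolated quantiles the
sample minimum and maximum always fall outside the closed interval, so
step 4 removes ≈ 1% of subjects plus the two extremes; on a 10-subject
toy this removes 2 of 10, which is the mathematically forced behaviour,
not a bug. Residual FFQ missingness is interpreted as non-consumption and
set to zero. Remaining missingness in other blocks is handled by a
median/mode fallback imputer — plumbing for the synthetic cohorts, not a
substitute for principled multiple imputation on real data, where global
missingness should first be shown to be small.

**Menstrual status.** Missing status is imputed "no" (ceased) iff
age > 50 years, strict; non-missing values pass through.

**Healthy+ mask.** HbA1c > 6.5, eGFR < 60 ml/min/1.73 m², or
UACR > 30 mg/g, strict inequalities. The HbA1c cut is applied on the
percent scale: 6.5% (≈ 48 mmol/mol) is the diagnostic convention, and a
threshold of 6.5 mmol/mol would be physiologically impossible. The
threshold is an argument for users who code HbA1c differently.

## Diet processing

FFQ categories map to portions/day via a fixed table — rarely/never 0,
1/month 1/30.44, 1/week 1/7, 2–4/week 3/7 (midpoint), 5–6/week 5.5/7
(midpoint), 1/day 1, 2+/day 2 — configurable, monotone in category
order. Grams/day = portions/day × grams/portion; group intakes sum member
items (mass-conserving); DASH components are 7 × portions/day
(servings/week) except sodium, computed as mg/day from per-100 g
densities over all items; TEI in kcal/day likewise.

Energy adjustment is the nutrient residual method: within each sex,
intake is regressed on TEI and replaced by residual + predicted intake at
the sex-mean TEI. The add-back constant keeps interpretable units and
preserves the within-sex mean; the quantile ranks the DASH score uses are
unaffected by it. The operation is idempotent and makes adjusted intake
exactly uncorrelated with TEI within sex.

## DASH score

Components are ranked within sex by empirical quantile cut-points
(linear interpolation), with half-open intervals (−∞, c₁], (c₁, c₂], … so
ties at a cut-point fall into the lower category — deterministic and
reproducible; an all-equal component degenerates to category 1 with a
warning. Healthy components score 1..k upward, unhealthy k..1 downward;
SSB uses tertiles because its distribution is dominated by zeros and low
intakes, and under the tie rule all zero consumers share the lowest
tertile (best rank 3 for an unhealthy item). The total is the sum of
eight ranks: minimum 8, maximum 5·7 + 3 = 38 under this scheme. The
implementation documents its achievable range rather than rescaling to
any nominal range; only the lower bound 8 is treated as structural.

## RRR engine

**Batch normalization.** Each mediator is quantile-normalized to its last
assay batch: within-batch values pass through their ecdf (average ranks,
plotting positions (r−1)/(n−1)) onto the reference batch's empirical
quantile function with linear interpolation. The reference batch is
untouched and within-batch rank order is preserved.

**Age/household adjustment.** Each mediator is residualized with the
random-intercept model y = β₀ + β₁·age + u_household + ε, u ~ N(0, σ_u²),
ε ~ N(0, σ_e²), fitted by one-dimensional minimization of the REML
criterion profiled over β and σ_e² (households partition subjects, so all
algebra is per-household closed form; the boundary σ_u = 0 is checked
explicitly and logged). The adjusted value subtracts both the fixed age
effect and the household BLUP; algebraically this equals V₀⁻¹·(GLS
residual), which is exactly orthogonal to the intercept and age columns.
A fixed-effects-only mode (`subtract_blup=False`) is provided because
"controlling for household" can be read either way; BLUP subtraction is
the default since it removes the shared household component from the
responses the patterns are fit to.

**Reduced-rank regression.** X (32 energy-adjusted group intakes) and Y
(9 adjusted mediators) are standardized within sex — standardization
happens after energy adjustment, within stratum. With B = (XᵀX)⁻¹XᵀY and
Ŷ = XB, response weights v_k are right singular vectors of Ŷ (SVD instead
of forming ŶᵀŶ, for stability), predictor weights a_k = B v_k, scores
s_k = X a_k = Ŷ v_k with eigenvalue λ_k = s_kᵀ s_k, and the explained
share of the first K patterns is Σλ_k / trace(YᵀY). Scores are pairwise
orthogonal by construction. Signs are fixed by making each a_k's
largest-magnitude entry positive. A near-singular XᵀX raises rather than
silently regularizing; the pipeline drops zero-variance food groups
(possible in small strata) before fitting, logging the count. Rank
selection replaces visual scree inspection with an explicit rule —
largest K with λ_K/λ₁ ≥ 0.10, capped at 2 — plus a "fixed" policy forcing
K = 2; the scree table is always written for human inspection.

## Association models

All exposures are z-standardized within the analysis stratum, so effects
read as ml/min/1.73 m² per 1-SD. Linear models are OLS with the fixed
confounder set (age, TEI, physical activity, smoking, education, BMI,
special diet); categorical covariates are dummy-coded against the
alphabetically first level; rank-deficient designs raise with the column
names. Slots for additional continuous confounders (e.g. genetic
principal components on real data) are just extra covariate columns.

The smooth model is eGFR = covariates + f₁(score) + f₂(age): cubic
B-spline bases (dimension 10, quantile knots, reduced automatically if
n/4 is smaller) with exact integrated-squared-second-derivative penalties
(two-point Gauss per knot span — exact because the second derivative is
piecewise linear). A sum-to-zero constraint is absorbed by a null-space
reparameterization, leaving the linear function as each penalty's
one-dimensional null space, so λ → ∞ collapses the smooth onto the
linear model exactly (`force_linear` implements that limit analytically).
The two λs are chosen jointly by Nelder-Mead on the profiled REML
criterion (n−M_p)·log D + log|XᵀX+S_λ| − Σ r_k log λ_k, seeded from a
coarse grid. Reported edf is the trace of the smooth's block of
(XᵀX+S_λ)⁻¹XᵀX. The smooth p-value is a Wald-type test of the penalized
coefficients at rank round(edf) — simpler than the test used by mature
GAM software and labelled approximate; the package's conclusions rest on
edf and effect recovery, not on p-value equality, and a unit test
cross-checks fitted values and edf against an independent GAM
implementation. α = 0.05 throughout, no multiplicity correction — the
grid is reported in full so readers can apply their own.

Interaction models (females) include score × menstrual-status and
score × age terms with all main effects and confounders. The modifier's
reference level defaults to "yes" (still menstruating), so the reported
coefficient is the additional effect per 1-SD in the ceased stratum,
matching the generative parameterization; recoding the reference flips
the sign only.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with planted, recoverable truth; one `numpy` Generator seeded from the
config drives everything, so identical configs give byte-identical
files.

Defaults (location/scale chosen to be realistic for a European adult
cohort): 53.4% female; age uniform 18–75; households of size 1–4
(probabilities 0.3/0.35/0.2/0.15); target energy intake
N(2050, 480) / N(1880, 440) kcal/day for males/females; 229 items in 32
groups of ~7, with lognormal portion sizes and energy/sodium densities,
and a toy item→DASH mapping (two groups per serving-based component,
clearly synthetic). Latent item rates are heavy-tailed across items (a
few daily staples, many rare foods), scale with the subject's target TEI,
and are calibrated so implied energy intake matches the target before
being discretized to the 7 FFQ categories by fixed cut-points at the
midpoints between category rates — the instrument's coarseness is part of
what downstream recovery is tested against. Menstrual status is
deterministic in age outside a stochastic 45–55 y transition band.

Two dietary directions d₁, d₂ per sex (orthonormal 32-vectors drawn from
the seed) define true pattern scores as standardized projections of the
energy-adjusted, standardized group intakes computed from the
*discretized* FFQ — i.e., from what the instrument records, the same
quantity the pipeline reconstructs — so planted truth is recoverable in
principle and attenuation reflects estimation, not an unbridgeable
latent-variable gap. Mediators are
location + scale·(0.3·z(age) + effect·w₁ᵐ·s₁ + 0.7·effect·w₂ᵐ·s₂ +
σ_house·u + σ_noise·ε) with per-mediator realistic locations/scales,
w₁ all-negative (pattern 1 lowers every biomarker) and w₂ orthogonalized
against w₁: with the two planted patterns orthogonal in both diet and
mediator space the RRR decomposition identifies them up to sign, which is
what makes recovery a sharp test. Assay batches are recruitment eras with
additive/multiplicative shifts, zero for the last (reference) batch.
eGFR is baseline(age, sex) + β_sex·s₁ + interaction·1[ceased]·s₁ + noise
(default β_male = 0.75, β_female = 0, interaction = 2.12 ml/min/1.73 m²
per 1-SD, noise SD 12), then creatinine is back-solved through the
CKD-EPI inverse. Disease flags are independent of diet so exclusions can
be exercised without confounding recovery. Missingness is sprinkled
item-wise plus a small fraction of heavy-missing subjects to exercise the
cascade.

**What passing tests show — and don't.** Recovery and calibration results
on these cohorts validate the estimators under the generator's
assumptions: linear diet→mediator and diet→eGFR structure, orthogonal
planted patterns, homoscedastic Gaussian noise, missingness completely at
random, no measurement-error correlation between diet and outcome, and
no seasonality or recall bias. Real FFQ data violate several of these;
the tests certify the machinery, not the epidemiology.

## Problem sizes used in validation

The validation suite uses cohorts of 5,000 for pattern recovery
(post-exclusion strata ≈ 1,900–2,100 per sex; recovery |corr| ≈ 0.997),
52,000 for effect recovery with eGFR noise SD 10 (male stratum ≈ 19,000,
slope SE ≈ 0.07), 200 replicates of 600 subjects for null-calibration
(type-I error, CI coverage, p-value uniformity), n = 5,000 regression
designs for edf behaviour, and the small fixtures stated next to each
oracle (n = 50 for the RRR numeric maximizer, 3×3 for the REML grid
search). These sizes are the package's own validation design and are
recomputed, not cached.

## Known limitations

* The smooth-term p-value is a simpler approximation than the
  Bayesian-covariance test in mature GAM software; edf values agree to a
  few tenths in cross-checks, p-values can differ more.
* The item→group and item→DASH-component mappings shipped with the
  generator are synthetic; real analyses must supply their own
  composition table.
* Bootstrap confidence intervals for loadings are not implemented.
* The mixed model supports a single random intercept (household); nested
  or crossed structures are out of scope.
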