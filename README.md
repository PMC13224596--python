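# dietkidney

Dietary-pattern analysis of kidney function for population-based
nutrition epidemiology: an a-priori diet-quality index (DASH) and hybrid,
disease-oriented dietary patterns (reduced rank regression, RRR) are
derived from food-frequency-questionnaire (FFQ) data and related to
creatinine-based estimated glomerular filtration rate (eGFR), with
sex-specific models and effect modification by menstrual status in
females. Because the cohort data such analyses run on are typically
access-restricted, the package ships a seeded synthetic-cohort generator
with planted, recoverable truth, so every stage is testable end to end.

Audience: biostatisticians and nutritional epidemiologists who want a
reproducible, tested implementation of this analysis pipeline — either to
run on their own cohort tables or to study the method's operating
characteristics on synthetic data.

## What it computes

**eGFR** from serum creatinine (mg/dL), age and sex via the race-free
CKD-EPI 2021 creatinine equation

    eGFR = 142 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^(−1.200) · 0.9938^age · 1.012[female]

with κ = 0.7/0.9 and α = −0.241/−0.302 for females/males.

**DASH score**: eight energy-adjusted food components (fruits, vegetables,
whole grains, low-fat dairy, nuts & legumes; red/processed meat, sodium,
sugar-sweetened beverages) are ranked into sex-specific quintiles —
tertiles for the sparsely consumed SSB component — scored upward for
healthy and downward for unhealthy components, and summed (minimum 8,
maximum 38 under this scheme). Energy adjustment uses the nutrient
residual method (within-sex regression on total energy intake).

**RRR dietary patterns**, per sex: nine mediator biomarkers (HbA1c, MAP,
CRP, uric acid, total cholesterol, ferritin, fibrinogen, potassium,
haemoglobin) are quantile-normalized across assay batches, residualized
on age and a household random intercept (REML linear mixed model), then
regressed on 32 standardized, energy-adjusted food-group intakes. With
B = (XᵀX)⁻¹XᵀY and Ŷ = XB, the k-th pattern weight is a_k = B v_k where
v_k is the k-th eigenvector of ŶᵀŶ; subject scores s_k = X a_k are
orthogonal by construction, and the number of retained patterns comes
from a scree-ratio rule (default cap 2).

**Association models**: OLS of eGFR on each z-standardized score plus
confounders (age, TEI, physical activity, smoking, education, BMI,
special diet), penalized-spline additive models with REML-selected
smoothing (effective degrees of freedom ≈ 1 means a linear relation),
score × menstrual-status and score × age interaction models in females,
the four-stratum analysis grid (males, females, menstruating, ceased),
and a "Healthy+" sensitivity repeat excluding sub-clinical disease
(HbA1c > 6.5%, eGFR < 60, or UACR > 30 mg/g).

## Worked example

```python
from dietkidney import CohortConfig, generate_cohort
from dietkidney.pipeline import prepare_sample, derive_scores, attach_scores
from dietkidney.association import fit_linear

cohort = generate_cohort(CohortConfig(n_subjects=5000, seed=2))
tables, report = prepare_sample(cohort)     # exclusions + eGFR
print(report.to_dict())
diet, dash, models, scores = derive_scores(tables)
print({s: round(m.explained_variance_share, 3) for s, m in models.items()})
df = attach_scores(tables, diet, dash, scores)
res = fit_linear(df[df.sex == "male"], "dp1")
print(round(res.beta, 2), tuple(round(c, 2) for c in res.ci95))
```

prints (seed 2):

```
{'input_n': 5000, 'removed_disease_or_medication': 957,
 'removed_missing_biomarkers': 2, 'removed_missing_ffq': 17,
 'removed_tei_bmr_range': 42, 'remaining_n': 3982}
{'male': 0.321, 'female': 0.295}
1.11 (0.55, 1.66)
```

The exclusion report partitions the input cohort; the explained-variance
shares are the fraction of adjusted-mediator variance captured by the two
retained patterns per sex; the final line is the first male dietary
pattern's effect on eGFR in ml/min/1.73 m² per 1-SD of the score with its
95% CI (the generator's default planted male effect is 0.75; at ~1,850
males the sampling SE is about 0.28, so the CI comfortably covers it).

The same run is available from the shell:

```sh
dietkidney generate --n 5000 --seed 2 --out cohort/
dietkidney prep --in cohort/ --out prep/
dietkidney analyse --in cohort/ --out results/
dietkidney run --config config.yaml        # full pipeline + manifest
```

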