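"""Seeded synthetic cohort generator.

Emulates the data blocks of a population-based nutrition/kidney study so
that the whole pipeline (FFQ processing, DASH scoring, RRR pattern
derivation, association models) can be exercised and validated without
access-restricted data. The generator plants known structure:

* item-level consumption frequencies correlated with total energy intake,
  discretized to the 7 FFQ categories;
* a toy composition/portion/mapping table (grams per portion, kcal and
  sodium densities, item -> food group and item -> DASH component);
* nine mediator biomarkers that depend linearly on two planted dietary
  directions (through the energy-adjusted, standardized food-group
  intakes), on age, and on a household random intercept, with assay-batch
  shifts relative to a reference batch;
* serum creatinine back-solved from a planted eGFR model
  eGFR = baseline(age, sex) + beta_sex * s1 + interaction * 1[ceased] * s1 + noise,
  so the association stage has a known truth, including a menstrual-status
  effect modification in females;
* covariates, disease/medication flags (independent of diet, so the
  exclusion cascade can be exercised without confounding recovery tests),
  and block-wise missingness.

Everything the recovery tests need (true directions, true per-subject
pattern scores, planted betas) is returned in ``SyntheticCohort.truth``
and written to ``truth.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_prep import compute_bmr, invert_egfr
from .diet_processing import (
    DASH_COMPONENTS,
    DEFAULT_FREQUENCY_MAP,
    FREQUENCY_CATEGORIES,
    build_diet_matrix,
    energy_adjust,
)
from .rrr_engine import MEDIATORS

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort",
           "write_cohort", "read_cohort"]


# per-mediator (location, scale) on the measurement scale
_MEDIATOR_BASE = {
    "hba1c": (5.3, 0.4),
    "map": (88.0, 9.0),
    "crp": (0.2, 0.12),
    "uric_acid": (5.2, 1.0),
    "tc": (203.0, 40.0),
    "ferritin": (85.0, 55.0),
    "fibrinogen": (290.0, 50.0),
    "potassium": (4.2, 0.35),
    "hgb": (14.8, 1.2),
}


@dataclass
class CohortConfig:
    """Generating parameters of a synthetic cohort.

    Effect sizes are expressed per 1-SD of the planted (sex-specific)
    dietary-pattern score: ``dp_effect_on_egfr`` in ml/min/1.73 m², with
    ``interaction_effect`` added in the ceased-menstruation stratum.
    ``effect_scale`` scales the diet -> mediator signal (in units of each
    mediator's SD); ``household_sd`` and ``noise_sd`` are the between-
    household and residual mediator SDs on the same standardized scale.
    """

    n_subjects: int = 5000
    seed: int = 0
    n_items: int = 229
    n_groups: int = 32
    sex_ratio: float = 0.534                      # proportion female
    age_range: tuple = (18.0, 75.0)
    household_size_dist: tuple = (0.3, 0.35, 0.2, 0.15)  # sizes 1..4
    tei_mean_sd_by_sex: dict = field(default_factory=lambda: {
        "male": (2050.0, 480.0), "female": (1880.0, 440.0)})
    effect_scale: float = 1.0
    secondary_effect_scale: float = 0.7
    household_sd: float = 0.5
    noise_sd: float = 1.0
    dp_effect_on_egfr: dict = field(default_factory=lambda: {
        "male": 0.75, "female": 0.0})
    interaction_effect: float = 2.12
    egfr_noise_sd: float = 12.0
    batch_count: int = 3
    missing_rates: dict = field(default_factory=lambda: {
        "ffq_item": 0.01, "ffq_heavy_subject": 0.004, "ffq_heavy_frac": 0.30,
        "biomarker": 0.01, "biomarker_heavy_subject": 0.001,
        "menstrual_status": 0.01})
    disease_flag_prevalence: dict = field(default_factory=lambda: {
        "kidney_disease": 0.02, "hypertension": 0.08, "diabetes": 0.03,
        "kidney_medication": 0.01, "hypertension_medication": 0.05,
        "diabetes_medication": 0.02})

    def __post_init__(self):
        errors = []
        if self.n_subjects < 4:
            errors.append("n_subjects: need at least 2 per downstream stratum")
        if not 0 < self.sex_ratio < 1:
            errors.append("sex_ratio: must lie strictly in (0, 1)")
        for name in ("household_sd", "noise_sd", "egfr_noise_sd",
                     "effect_scale", "secondary_effect_scale"):
            if getattr(self, name) < 0:
                errors.append(f"{name}: must be >= 0")
        if self.n_items < self.n_groups:
            errors.append("n_items: must be >= n_groups")
        if self.batch_count < 1:
            errors.append("batch_count: must be >= 1")
        if abs(sum(self.household_size_dist) - 1.0) > 1e-9:
            errors.append("household_size_dist: probabilities must sum to 1")
        if errors:
            raise ValueError("invalid CohortConfig: " + "; ".join(errors))


@dataclass
class SyntheticCohort:
    """Generated tables plus the generating truth."""

    ffq: pd.DataFrame
    composition: pd.DataFrame
    biomarkers: pd.DataFrame
    creatinine: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict


def _make_composition(cfg: CohortConfig, rng) -> pd.DataFrame:
    items = [f"item_{i + 1:03d}" for i in range(cfg.n_items)]
    group_idx = np.sort(np.arange(cfg.n_items) % cfg.n_groups)
    groups = [f"group_{g + 1:02d}" for g in group_idx]
    grams = np.clip(np.exp(rng.normal(np.log(80.0), 0.5, cfg.n_items)), 10, 400)
    kcal = rng.uniform(20.0, 400.0, cfg.n_items)
    sodium = np.clip(np.exp(rng.normal(np.log(150.0), 1.0, cfg.n_items)), 1, 2000)
    # toy item -> DASH mapping: 7 serving-based components get 2 groups each
    # (sodium is computed from densities over all items, not from members)
    serving_comps = [c for c in DASH_COMPONENTS if c != "sodium"]
    comp_of_group = {}
    for d, comp in enumerate(serving_comps):
        comp_of_group[2 * d] = comp
        comp_of_group[2 * d + 1] = comp
    dash = [comp_of_group.get(g, "") for g in group_idx]
    return pd.DataFrame({
        "item_id": items,
        "grams_per_portion": np.round(grams, 1),
        "group_id": groups,
        "dash_component": dash,
        "sodium_mg_per_100g": np.round(sodium, 1),
        "kcal_per_100g": np.round(kcal, 1),
    })


# FFQ discretization: fixed cut-points on the portions/day scale, at the
# midpoints between consecutive category rates
_CAT_VALUES = np.array([DEFAULT_FREQUENCY_MAP[c] for c in FREQUENCY_CATEGORIES])
_CAT_CUTS = (_CAT_VALUES[:-1] + _CAT_VALUES[1:]) / 2.0


def _orthonormal_pair(rng, p):
    d1 = rng.normal(size=p)
    d1 /= np.linalg.norm(d1)
    d2 = rng.normal(size=p)
    d2 -= d1 * (d1 @ d2)
    d2 /= np.linalg.norm(d2)
    return d1, d2


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one synthetic cohort; deterministic for a fixed config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    subject_id = [f"S{i + 1:06d}" for i in range(n)]

    # households
    sizes = rng.choice(np.arange(1, len(cfg.household_size_dist) + 1),
                       size=n, p=cfg.household_size_dist)
    hh_ids, total = [], 0
    h = 0
    while total < n:
        hh_ids.extend([h] * int(sizes[h % n]))
        total += int(sizes[h % n])
        h += 1
    household = np.array([f"H{i:05d}" for i in hh_ids[:n]])

    # demographics
    female = rng.random(n) < cfg.sex_ratio
    sex = np.where(female, "female", "male")
    age = rng.uniform(*cfg.age_range, size=n)
    # menstrual status: deterministic by age with a stochastic 45-55 band
    p_ceased = np.clip((age - 45.0) / 10.0, 0.0, 1.0)
    ceased = female & (rng.random(n) < p_ceased)
    menstrual_true = np.where(female, np.where(ceased, "no", "yes"),
                              "not_applicable")

    height = np.where(female, rng.normal(165.0, 6.5, n), rng.normal(178.0, 7.0, n))
    bmi = np.where(female, rng.normal(24.0, 3.8, n), rng.normal(25.5, 3.3, n))
    bmi = np.clip(bmi, 16.0, 45.0)
    weight = bmi * (height / 100.0) ** 2
    bmr = compute_bmr(sex, age, weight)

    tei_target = np.where(
        female,
        rng.normal(*cfg.tei_mean_sd_by_sex["female"], size=n),
        rng.normal(*cfg.tei_mean_sd_by_sex["male"], size=n),
    )
    tei_target = np.clip(tei_target, 800.0, None)

    # composition + latent intakes
    composition = _make_composition(cfg, rng)
    # heavy-tailed across items: a few daily staples, many rarely-eaten foods
    base_rate = np.minimum(np.exp(rng.normal(np.log(0.05), 1.5, cfg.n_items)), 2.0)
    ssb_items = (composition["dash_component"] == "ssb").to_numpy()
    base_rate[ssb_items] *= 0.3  # SSB intake sparse by design
    # calibrate base rates so the implied energy intake sits at the target
    # (kcal/portion per item; 1.197 = mean of the lognormal intake noise)
    kcal_per_portion = (composition["grams_per_portion"].to_numpy()
                        * composition["kcal_per_100g"].to_numpy() / 100.0)
    base_rate *= tei_target.mean() / (base_rate @ kcal_per_portion * 1.197)
    tei_rel = tei_target / tei_target.mean()
    latent = (base_rate[None, :] * tei_rel[:, None]
              * np.exp(rng.normal(0.0, 0.6, size=(n, cfg.n_items))))
    codes = np.searchsorted(_CAT_CUTS, latent, side="right")  # 0..6

    # FFQ missingness: sparse item-level plus a few heavy-missing subjects
    mr = cfg.missing_rates
    ffq = codes.astype(float)
    miss_mask = rng.random((n, cfg.n_items)) < mr["ffq_item"]
    heavy = rng.random(n) < mr["ffq_heavy_subject"]
    heavy_items = rng.random((n, cfg.n_items)) < mr["ffq_heavy_frac"]
    miss_mask |= heavy[:, None] & heavy_items
    ffq[miss_mask] = np.nan
    ffq_df = pd.DataFrame(ffq, columns=composition["item_id"].tolist())
    ffq_df.insert(0, "subject_id", subject_id)

    # diet matrix as the pipeline will see it (missing -> 0)
    ffq_filled = ffq_df.copy()
    item_cols = composition["item_id"].tolist()
    ffq_filled[item_cols] = ffq_filled[item_cols].fillna(0)
    diet = build_diet_matrix(ffq_filled, composition)
    tei_computed = diet.tei.to_numpy()
    # guard against degenerate zero-energy reporters in downstream regressions
    tei_computed = np.maximum(tei_computed, 1.0)

    X_adj = energy_adjust(diet.group_intake, tei_computed, sex)
    truth_scores = np.zeros(n)
    truth_scores2 = np.zeros(n)
    directions = {}
    q = len(MEDIATORS)
    mediator_signal = np.zeros((n, q))
    w_store = {}
    for s in ("male", "female"):
        m = sex == s
        Xs = X_adj.loc[m].to_numpy()
        mu, sd = Xs.mean(0), Xs.std(0, ddof=1)
        sd[sd <= 0] = 1.0
        Xs = (Xs - mu) / sd
        d1, d2 = _orthonormal_pair(rng, cfg.n_groups)
        s1 = Xs @ d1
        s2 = Xs @ d2
        s1 = (s1 - s1.mean()) / (s1.std(ddof=1) or 1.0)
        s2 = (s2 - s2.mean()) / (s2.std(ddof=1) or 1.0)
        truth_scores[m] = s1
        truth_scores2[m] = s2
        # mediator response weights: pattern 1 lowers every biomarker;
        # pattern 2 is orthogonalized against it so the two planted
        # patterns are identifiable (orthogonal in diet AND mediator space)
        w1 = -np.abs(rng.normal(0.7, 0.15, q))
        w2 = rng.normal(0.0, 0.6, q)
        w1_hat = w1 / np.linalg.norm(w1)
        w2 = w2 - w1_hat * (w1_hat @ w2)
        mediator_signal[m] = (cfg.effect_scale * np.outer(s1, w1)
                              + cfg.secondary_effect_scale * np.outer(s2, w2))
        directions[s] = {"d1": d1.tolist(), "d2": d2.tolist()}
        w_store[s] = {"w1": w1.tolist(), "w2": w2.tolist()}

    # mediators: location + age trend + planted diet signal + household + noise
    uniq_hh, hh_inv = np.unique(household, return_inverse=True)
    med = {}
    for j, name in enumerate(MEDIATORS):
        loc, scale = _MEDIATOR_BASE[name]
        u = rng.normal(0.0, 1.0, uniq_hh.size)[hh_inv]
        e = rng.normal(0.0, 1.0, n)
        std_val = (0.3 * (age - age.mean()) / age.std()
                   + mediator_signal[:, j]
                   + cfg.household_sd * u + cfg.noise_sd * e)
        med[name] = loc + scale * std_val

    # assay batches: contiguous recruitment eras, last batch = reference
    era = rng.permutation(n) * cfg.batch_count // n + 1
    batch_labels = np.array([f"B{b}" for b in era])
    bio = pd.DataFrame(med)
    for j, name in enumerate(MEDIATORS):
        shift = np.linspace(0.4, 0.0, cfg.batch_count)   # reference batch: 0
        scale_eff = np.linspace(1.1, 1.0, cfg.batch_count)
        loc, scale = _MEDIATOR_BASE[name]
        b_idx = era - 1
        bio[name] = loc + (bio[name] - loc) * scale_eff[b_idx] \
            + scale * shift[b_idx]
        bio[f"batch_{name}"] = batch_labels
    # biomarker missingness
    med_cols = list(MEDIATORS)
    miss_b = rng.random((n, q)) < mr["biomarker"]
    heavy_b = rng.random(n) < mr["biomarker_heavy_subject"]
    miss_b |= heavy_b[:, None] & (rng.random((n, q)) < 0.95)
    vals = bio[med_cols].to_numpy()
    vals[miss_b] = np.nan
    bio[med_cols] = vals
    bio.insert(0, "subject_id", subject_id)

    # planted eGFR and back-solved creatinine
    beta = np.where(female, cfg.dp_effect_on_egfr["female"],
                    cfg.dp_effect_on_egfr["male"])
    baseline = np.where(female, 112.0, 115.0) - 0.45 * age
    egfr_true = (baseline + beta * truth_scores
                 + cfg.interaction_effect * ceased * truth_scores
                 + rng.normal(0.0, cfg.egfr_noise_sd, n))
    egfr_true = np.clip(egfr_true, 8.0, 170.0)
    creat = invert_egfr(egfr_true, age, sex)
    creatinine = pd.DataFrame({"subject_id": subject_id,
                               "creatinine": np.round(creat, 6)})

    # covariates
    menstrual = menstrual_true.astype(object)
    miss_m = female & (rng.random(n) < mr["menstrual_status"])
    menstrual[miss_m] = "missing"
    flags = {k: (rng.random(n) < p).astype(int)
             for k, p in cfg.disease_flag_prevalence.items()}
    uacr = np.exp(rng.normal(np.log(8.0), 0.8, n))
    covariates = pd.DataFrame({
        "subject_id": subject_id,
        "age": np.round(age, 2),
        "sex": sex,
        "bmi": np.round(bmi, 2),
        "height": np.round(height, 1),
        "weight": np.round(weight, 2),
        "physical_activity": np.round(np.exp(rng.normal(np.log(3300.0), 0.7, n)), 1),
        "smoking": rng.choice(["never", "current", "past"], size=n,
                              p=[0.55, 0.20, 0.25]),
        "education": rng.choice(
            ["primary", "lower_secondary", "vocational", "upper_secondary",
             "university"], size=n, p=[0.05, 0.15, 0.40, 0.27, 0.13]),
        "special_diet": rng.choice(["no", "yes"], size=n, p=[0.96, 0.04]),
        "household_id": household,
        "menstrual_status": menstrual,
        "tei": np.round(tei_computed, 3),
        "bmr": np.round(bmr, 3),
        "uacr": np.round(uacr, 3),
        **flags,
    })

    truth = {
        "seed": cfg.seed,
        "n_subjects": n,
        "directions": directions,
        "mediator_weights": w_store,
        "effect_scale": cfg.effect_scale,
        "secondary_effect_scale": cfg.secondary_effect_scale,
        "household_sd": cfg.household_sd,
        "noise_sd": cfg.noise_sd,
        "dp_effect_on_egfr": dict(cfg.dp_effect_on_egfr),
        "interaction_effect": cfg.interaction_effect,
        "egfr_noise_sd": cfg.egfr_noise_sd,
        "subject_id": subject_id,
        "true_score_dp1": np.round(truth_scores, 8).tolist(),
        "true_score_dp2": np.round(truth_scores2, 8).tolist(),
        "true_menstrual_status": menstrual_true.tolist(),
        "true_egfr": np.round(egfr_true, 6).tolist(),
    }
    return SyntheticCohort(ffq=ffq_df, composition=composition, biomarkers=bio,
                           creatinine=creatinine, covariates=covariates,
                           truth=truth)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TABLES = {
    "ffq": ("ffq.csv", ","),
    "composition": ("composition.tsv", "\t"),
    "biomarkers": ("biomarkers.csv", ","),
    "creatinine": ("creatinine.csv", ","),
    "covariates": ("covariates.csv", ","),
}


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort tables (CSV/TSV) and truth.json into `directory`."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {directory}")
    paths = {}
    for name, (fname, sep) in _TABLES.items():
        path = directory / fname
        getattr(cohort, name).to_csv(path, sep=sep, index=False)
        paths[name] = path
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(cohort.truth, indent=1))
    paths["truth"] = truth_path
    return paths


def read_cohort(directory) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    frames = {}
    for name, (fname, sep) in _TABLES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"missing cohort file: {path}")
        frames[name] = pd.read_csv(path, sep=sep, keep_default_na=True,
                                   na_values=[""], dtype={"subject_id": str})
    frames["composition"]["dash_component"] = (
        frames["composition"]["dash_component"].fillna(""))
    truth = json.loads((directory / "truth.json").read_text())
    return SyntheticCohort(truth=truth, **frames)
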