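"""Cohort preparation: eGFR computation, exclusion cascade, classification rules.

This module turns raw per-subject tables (FFQ, biomarkers, covariates,
creatinine) into the analysis-ready sample:

* kidney function (eGFR) from serum creatinine via the race-free CKD-EPI
  2021 creatinine equation;
* basal metabolic rate (BMR) from Schofield's age-sex-band equations, used
  to screen implausible energy reporting via the TEI/BMR ratio;
* menstrual-status imputation for females with missing status;
* a fixed-order exclusion cascade (disease/medication self-report, sparse
  biomarkers, sparse FFQ, extreme TEI/BMR ratio) with a per-step report;
* the "Healthy+" sensitivity mask (sub-clinical diabetes, reduced eGFR or
  albuminuria).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EGFRParams",
    "ExclusionReport",
    "ExclusionThresholds",
    "compute_egfr",
    "invert_egfr",
    "compute_bmr",
    "impute_menstrual_status",
    "apply_exclusions",
    "simple_impute",
    "flag_healthy_plus",
]


# ---------------------------------------------------------------------------
# eGFR — CKD-EPI 2021 creatinine equation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EGFRParams:
    """Constants of the CKD-EPI 2021 creatinine equation.

    eGFR = level_constant * min(scr/kappa, 1)^alpha * max(scr/kappa, 1)^(-1.200)
           * age_decay^age * (female_multiplier if female)

    with sex-specific kappa (mg/dL) and alpha.
    """

    kappa: dict = field(default_factory=lambda: {"male": 0.9, "female": 0.7})
    alpha: dict = field(default_factory=lambda: {"male": -0.302, "female": -0.241})
    high_exponent: float = -1.200
    age_decay: float = 0.9938
    female_multiplier: float = 1.012
    level_constant: float = 142.0

    def __post_init__(self):
        if any(v <= 0 for v in self.kappa.values()):
            raise ValueError("kappa must be positive")
        if not 0 < self.age_decay < 1:
            raise ValueError("age_decay must lie in (0, 1)")


def _as_female_mask(sex) -> np.ndarray:
    sex = np.asarray(sex)
    if sex.dtype.kind in "UOS":
        return np.char.lower(sex.astype(str)) == "female"
    return sex.astype(bool)


def compute_egfr(creatinine, age, sex, params: EGFRParams | None = None):
    """Estimated glomerular filtration rate, ml/min/1.73 m².

    Parameters
    ----------
    creatinine : array-like, serum creatinine in mg/dL (must be > 0).
    age : array-like, years (must be > 0).
    sex : array-like of {"male", "female"} (or boolean, True = female).
    """
    p = params or EGFRParams()
    scr = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("creatinine must be positive (mg/dL)")
    if np.any(age <= 0):
        raise ValueError("age must be positive (years)")
    female = _as_female_mask(sex)
    kappa = np.where(female, p.kappa["female"], p.kappa["male"])
    alpha = np.where(female, p.alpha["female"], p.alpha["male"])
    ratio = scr / kappa
    egfr = (
        p.level_constant
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** p.high_exponent
        * p.age_decay ** age
        * np.where(female, p.female_multiplier, 1.0)
    )
    if np.isscalar(creatinine) and np.isscalar(age):
        return float(egfr)
    return egfr


def invert_egfr(egfr, age, sex, params: EGFRParams | None = None):
    """Serum creatinine (mg/dL) that yields the given eGFR under CKD-EPI 2021.

    The equation is continuous and strictly decreasing in creatinine, so the
    inverse is unique: the piece (below vs above kappa) is chosen by comparing
    the target against the value at scr = kappa.
    """
    p = params or EGFRParams()
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("eGFR must be positive")
    female = _as_female_mask(sex)
    kappa = np.where(female, p.kappa["female"], p.kappa["male"])
    alpha = np.where(female, p.alpha["female"], p.alpha["male"])
    # eGFR at scr == kappa (both ratio factors equal 1)
    at_kappa = (
        p.level_constant
        * p.age_decay ** age
        * np.where(female, p.female_multiplier, 1.0)
    )
    rel = egfr / at_kappa
    # rel >= 1  -> low-creatinine branch (exponent alpha < 0)
    scr = np.where(
        rel >= 1.0,
        kappa * rel ** (1.0 / alpha),
        kappa * rel ** (1.0 / p.high_exponent),
    )
    return scr


# ---------------------------------------------------------------------------
# BMR — Schofield weight-based equations
# ---------------------------------------------------------------------------

# kcal/day; bands [10,18), [18,30], (30,60), (60, inf)
_SCHOFIELD = {
    "male": [
        (10.0, 18.0, 17.686, 658.2),
        (18.0, 30.0, 15.057, 692.2),
        (30.0, 60.0, 11.472, 873.1),
        (60.0, np.inf, 11.711, 587.7),
    ],
    "female": [
        (10.0, 18.0, 13.384, 692.6),
        (18.0, 30.0, 14.818, 486.6),
        (30.0, 60.0, 8.126, 845.6),
        (60.0, np.inf, 9.082, 658.5),
    ],
}


def compute_bmr(sex, age, weight, height=None, equation: str = "schofield"):
    """Basal metabolic rate, kcal/day.

    Default equation is Schofield's weight-only age-sex-band formula
    (BMR = a * weight + b). `height` (cm) is accepted for interface parity
    with height-based equations but unused by the Schofield bands. Band
    edges: [10, 18) adolescent, [18, 30] young adult, (30, 60) middle,
    [60, inf) older.
    """
    if equation != "schofield":
        raise ValueError(f"unsupported BMR equation: {equation!r}")
    age = np.asarray(age, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if np.any(age <= 0) or np.any(weight <= 0):
        raise ValueError("age and weight must be positive")
    scalar = age.ndim == 0 and weight.ndim == 0
    female = _as_female_mask(sex)
    age_b, weight_b, female_b = map(
        np.atleast_1d, np.broadcast_arrays(age, weight, female)
    )
    # band index: <18 adolescent (extrapolated below 10), [18,30], (30,60), >=60
    band = np.select(
        [age_b < 18.0, age_b <= 30.0, age_b < 60.0], [0, 1, 2], default=3
    )
    out = np.empty(age_b.shape, dtype=float)
    for is_f, key in ((False, "male"), (True, "female")):
        for i, (_, _, a, b) in enumerate(_SCHOFIELD[key]):
            m = (female_b == is_f) & (band == i)
            out[m] = a * weight_b[m] + b
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Menstrual-status imputation
# ---------------------------------------------------------------------------

def impute_menstrual_status(status, age):
    """Fill missing menstrual status by age: missing -> "no" iff age > 50.

    Non-missing values pass through unchanged. "Missing" means the string
    "missing", None, or NaN.
    """
    status_arr = pd.Series(np.atleast_1d(np.asarray(status, dtype=object)))
    age_arr = np.atleast_1d(np.asarray(age, dtype=float))
    if np.any(age_arr <= 0):
        raise ValueError("age must be positive")
    is_missing = status_arr.isna() | (status_arr.astype(str).str.lower() == "missing")
    out = status_arr.astype(object).copy()
    out[is_missing] = np.where(age_arr[is_missing.to_numpy()] > 50.0, "no", "yes")
    if np.isscalar(status) or status is None:
        return out.iloc[0]
    return out.to_numpy()


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionThresholds:
    """Cut-offs of the exclusion cascade."""

    max_missing_biomarker_frac: float = 0.80   # step 2: strictly more than this
    max_missing_ffq_frac: float = 0.20         # step 3: strictly more than this
    tei_bmr_lower_q: float = 0.005             # step 4 percentile interval
    tei_bmr_upper_q: float = 0.995


@dataclass
class ExclusionReport:
    """Per-step removal counts; steps are applied in the listed order."""

    input_n: int
    removed_disease_or_medication: int
    removed_missing_biomarkers: int
    removed_missing_ffq: int
    removed_tei_bmr_range: int
    remaining_n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def check_partition(self) -> bool:
        removed = (
            self.removed_disease_or_medication
            + self.removed_missing_biomarkers
            + self.removed_missing_ffq
            + self.removed_tei_bmr_range
        )
        return removed + self.remaining_n == self.input_n


_DISEASE_FLAGS = [
    "kidney_disease",
    "hypertension",
    "diabetes",
    "kidney_medication",
    "hypertension_medication",
    "diabetes_medication",
]


def apply_exclusions(cohort, thresholds: ExclusionThresholds | None = None):
    """Apply the fixed exclusion cascade; return (prepared tables, report).

    `cohort` is any object exposing DataFrames `ffq` (subject_id +
    item_* columns, NaN = missing), `biomarkers`, and `covariates`
    (with disease/medication flags, `tei`, and `bmr` columns), all keyed by
    `subject_id` — e.g. a :class:`~dietkidney.synthetic_cohort.SyntheticCohort`.

    Cascade order (fixed):
      1. any self-reported kidney disease / hypertension / diabetes or a
         corresponding medication;
      2. > 80% missing biomarker columns;
      3. > 20% missing FFQ items;
      4. TEI/BMR ratio outside the closed [0.5th, 99.5th] percentile interval
         computed on the sample surviving step 3.

    Remaining FFQ missing values are set to zero (assumed non-consumption).
    Returns a dict of filtered copies of every table attached to the cohort
    plus the :class:`ExclusionReport`.
    """
    thr = thresholds or ExclusionThresholds()
    cov = cohort.covariates.set_index("subject_id")
    ffq = cohort.ffq.set_index("subject_id")
    bio = cohort.biomarkers.set_index("subject_id")
    item_cols = [c for c in ffq.columns if c.startswith("item_")]
    bio_cols = [c for c in bio.columns if not c.startswith("batch_")]
    input_n = len(cov)
    keep = cov.index

    # step 1: disease / medication self-report
    flags_present = [c for c in _DISEASE_FLAGS if c in cov.columns]
    flagged = cov[flags_present].astype(bool).any(axis=1)
    n1 = int(flagged.loc[keep].sum())
    keep = keep[~flagged.loc[keep].to_numpy()]
    if len(keep) == 0:
        raise ValueError("empty sample after exclusion step 1 (disease/medication)")

    # step 2: sparse biomarkers
    bio_missing_frac = bio.loc[keep, bio_cols].isna().mean(axis=1)
    drop2 = bio_missing_frac > thr.max_missing_biomarker_frac
    n2 = int(drop2.sum())
    keep = keep[~drop2.to_numpy()]
    if len(keep) == 0:
        raise ValueError("empty sample after exclusion step 2 (missing biomarkers)")

    # step 3: sparse FFQ
    ffq_missing_frac = ffq.loc[keep, item_cols].isna().mean(axis=1)
    drop3 = ffq_missing_frac > thr.max_missing_ffq_frac
    n3 = int(drop3.sum())
    keep = keep[~drop3.to_numpy()]
    if len(keep) == 0:
        raise ValueError("empty sample after exclusion step 3 (missing FFQ)")

    # step 4: TEI/BMR percentile interval on the post-step-3 sample
    ratio = (cov.loc[keep, "tei"] / cov.loc[keep, "bmr"]).to_numpy(dtype=float)
    lo = np.quantile(ratio, thr.tei_bmr_lower_q)  # linear interpolation default
    hi = np.quantile(ratio, thr.tei_bmr_upper_q)
    inside = (ratio >= lo) & (ratio <= hi)
    n4 = int((~inside).sum())
    keep = keep[inside]
    if len(keep) == 0:
        raise ValueError("empty sample after exclusion step 4 (TEI/BMR range)")

    report = ExclusionReport(
        input_n=input_n,
        removed_disease_or_medication=n1,
        removed_missing_biomarkers=n2,
        removed_missing_ffq=n3,
        removed_tei_bmr_range=n4,
        remaining_n=len(keep),
    )

    out = {}
    for name in ("ffq", "biomarkers", "covariates", "creatinine"):
        table = getattr(cohort, name, None)
        if table is None:
            continue
        sub = table.set_index("subject_id").loc[keep].reset_index()
        out[name] = sub
    if getattr(cohort, "composition", None) is not None:
        out["composition"] = cohort.composition.copy()  # not subject-keyed
    # residual FFQ missingness -> zero (non-consumption)
    out["ffq"][item_cols] = out["ffq"][item_cols].fillna(0)
    return out, report


def simple_impute(df: pd.DataFrame) -> pd.DataFrame:
    """Median (numeric) / mode (other) fallback imputer for residual
    missingness after the exclusion cascade. Plumbing only — not a
    substitute for principled multiple imputation on real data."""
    out = df.copy()
    for c in out.columns:
        if not out[c].isna().any():
            continue
        if pd.api.types.is_numeric_dtype(out[c]):
            out[c] = out[c].fillna(out[c].median())
        else:
            out[c] = out[c].fillna(out[c].mode().iloc[0])
    return out


# ---------------------------------------------------------------------------
# Healthy+ sensitivity mask
# ---------------------------------------------------------------------------

def flag_healthy_plus(hba1c, egfr, uacr, hba1c_threshold: float = 6.5):
    """Mask of subjects excluded from the Healthy+ sensitivity sample.

    True where HbA1c > threshold (percent scale) OR eGFR < 60 ml/min/1.73 m²
    OR urinary albumin-to-creatinine ratio > 30 mg/g; strict inequalities.
    """
    if uacr is None:
        raise ValueError(
            "UACR column missing: Healthy+ sensitivity analysis unavailable"
        )
    hba1c = np.asarray(hba1c, dtype=float)
    egfr = np.asarray(egfr, dtype=float)
    uacr = np.asarray(uacr, dtype=float)
    return (hba1c > hba1c_threshold) | (egfr < 60.0) | (uacr > 30.0)
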