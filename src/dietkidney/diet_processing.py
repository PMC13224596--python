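"""FFQ processing: frequencies → grams/day, food-group and DASH-component
aggregation, total energy intake, and nutrient-residual energy adjustment.

The food-frequency questionnaire records, for each of 229 items, one of
seven ordered consumption categories. Each category maps to a fixed
portions/day rate; grams/day follow from a per-item portion size, nutrient
totals from per-100 g densities, and the 229 items aggregate into 32
food groups (g/day, for pattern derivation) and 8 DASH components
(servings/week; sodium as mg/day).

Energy adjustment uses the nutrient residual method: within each sex, an
intake is replaced by its residual from a simple linear regression on total
energy intake (TEI), plus the predicted intake at the sex-mean TEI so units
and location stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FREQUENCY_CATEGORIES",
    "DEFAULT_FREQUENCY_MAP",
    "DASH_COMPONENTS",
    "DietMatrix",
    "frequency_to_daily",
    "build_diet_matrix",
    "energy_adjust",
]

# ordered categories, coded 0..6 in the data files
FREQUENCY_CATEGORIES = (
    "rarely/never",
    "1/month",
    "1/week",
    "2-4/week",
    "5-6/week",
    "1/day",
    "2+/day",
)

# portions/day per category; midpoints for ranges, 30.44 d/month
DEFAULT_FREQUENCY_MAP = {
    "rarely/never": 0.0,
    "1/month": 1.0 / 30.44,
    "1/week": 1.0 / 7.0,
    "2-4/week": 3.0 / 7.0,
    "5-6/week": 5.5 / 7.0,
    "1/day": 1.0,
    "2+/day": 2.0,
}

# the 8 Fung-style DASH components; direction and ranking scheme live here
# (sodium is a continuous nutrient in mg/day, all others servings/week)
DASH_COMPONENTS = {
    "fruits": ("healthy", "quintile"),
    "vegetables": ("healthy", "quintile"),
    "whole_grains": ("healthy", "quintile"),
    "low_fat_dairy": ("healthy", "quintile"),
    "nuts_legumes": ("healthy", "quintile"),
    "red_processed_meat": ("unhealthy", "quintile"),
    "sodium": ("unhealthy", "quintile"),
    "ssb": ("unhealthy", "tertile"),
}


def frequency_to_daily(category, freq_map: dict | None = None):
    """Convert a frequency category (label or integer code 0–6) to portions/day."""
    fmap = DEFAULT_FREQUENCY_MAP if freq_map is None else freq_map
    if isinstance(category, str):
        if category not in fmap:
            raise ValueError(f"unknown frequency category: {category!r}")
        return fmap[category]
    code = int(category)
    if not 0 <= code < len(FREQUENCY_CATEGORIES):
        raise ValueError(f"frequency code out of range 0..6: {category!r}")
    return fmap[FREQUENCY_CATEGORIES[code]]


@dataclass
class DietMatrix:
    """Per-subject dietary intakes derived from the FFQ.

    Attributes
    ----------
    group_intake : DataFrame, 32 food-group columns in g/day (subject_id index).
    dash_components : DataFrame, 8 component columns — servings/week except
        sodium (mg/day).
    tei : Series, total energy intake kcal/day.
    group_intake_adjusted, dash_components_adjusted : energy-adjusted
        counterparts (None until :func:`energy_adjust` is applied).
    """

    group_intake: pd.DataFrame
    dash_components: pd.DataFrame
    tei: pd.Series
    group_intake_adjusted: pd.DataFrame | None = None
    dash_components_adjusted: pd.DataFrame | None = None


def _portions_per_day(ffq: pd.DataFrame, item_cols, freq_map) -> np.ndarray:
    fmap = DEFAULT_FREQUENCY_MAP if freq_map is None else freq_map
    lut = np.array([fmap[c] for c in FREQUENCY_CATEGORIES], dtype=float)
    codes = ffq[item_cols].to_numpy()
    if np.isnan(codes.astype(float)).any():
        raise ValueError("FFQ contains missing codes; impute (zero) before conversion")
    codes = codes.astype(int)
    if codes.min() < 0 or codes.max() >= len(lut):
        raise ValueError("FFQ codes outside the 7-category range 0..6")
    return lut[codes]


def build_diet_matrix(
    ffq: pd.DataFrame, composition: pd.DataFrame, freq_map: dict | None = None
) -> DietMatrix:
    """Aggregate item frequencies to group intakes, DASH components and TEI.

    Parameters
    ----------
    ffq : DataFrame with `subject_id` and item_* columns holding the integer
        frequency codes 0..6 (missing values must already be imputed).
    composition : DataFrame with one row per item: `item_id`,
        `grams_per_portion`, `group_id`, `dash_component` (may be empty/NaN),
        `sodium_mg_per_100g`, `kcal_per_100g`.
    """
    item_cols = [c for c in ffq.columns if c.startswith("item_")]
    comp = composition.set_index("item_id")
    missing = [c for c in item_cols if c not in comp.index]
    if missing:
        raise ValueError(f"items missing from composition table: {missing[:5]}...")
    comp = comp.loc[item_cols]
    for col in ("grams_per_portion", "sodium_mg_per_100g", "kcal_per_100g"):
        if (comp[col] < 0).any():
            raise ValueError(f"negative values in composition column {col}")

    portions = _portions_per_day(ffq, item_cols, freq_map)  # n x 229
    grams = portions * comp["grams_per_portion"].to_numpy()  # g/day

    idx = pd.Index(ffq["subject_id"], name="subject_id")
    groups = sorted(comp["group_id"].unique())
    group_df = pd.DataFrame(
        {g: grams[:, (comp["group_id"] == g).to_numpy()].sum(axis=1) for g in groups},
        index=idx,
    )

    dash = {}
    for comp_name in DASH_COMPONENTS:
        members = (comp["dash_component"] == comp_name).to_numpy()
        if comp_name == "sodium":
            continue
        dash[comp_name] = 7.0 * portions[:, members].sum(axis=1)  # servings/week
    # sodium: total mg/day over all items, from density
    sodium = (grams * comp["sodium_mg_per_100g"].to_numpy() / 100.0).sum(axis=1)
    dash["sodium"] = sodium
    dash_df = pd.DataFrame(dash, index=idx)[list(DASH_COMPONENTS)]

    tei = pd.Series(
        (grams * comp["kcal_per_100g"].to_numpy() / 100.0).sum(axis=1),
        index=idx,
        name="tei",
    )
    return DietMatrix(group_intake=group_df, dash_components=dash_df, tei=tei)


def energy_adjust(values, tei, sex):
    """Nutrient-residual energy adjustment, computed within sex.

    For each sex stratum and each intake column: regress intake on TEI
    (simple OLS), keep the residual, and add back the predicted intake at
    the sex-specific mean TEI. The adjusted intake is uncorrelated with TEI
    within sex and preserves the within-sex mean.

    Parameters
    ----------
    values : Series or DataFrame of intakes (rows = subjects).
    tei : array-like kcal/day, aligned with `values` rows.
    sex : array-like of {"male","female"}, aligned with `values` rows.

    Returns an object of the same type/shape as `values`.
    """
    frame = values.to_frame() if isinstance(values, pd.Series) else values
    X = frame.to_numpy(dtype=float)
    tei = np.asarray(tei, dtype=float)
    sex = np.asarray(sex)
    out = np.empty_like(X)
    for s in np.unique(sex):
        m = sex == s
        if m.sum() < 3:
            raise ValueError(f"need >= 3 subjects per sex for energy adjustment ({s})")
        t = tei[m]
        tc = t - t.mean()
        denom = float(tc @ tc)
        if denom <= 0:
            raise ValueError(f"zero TEI variance within sex {s}: slope undefined")
        Xm = X[m]
        slopes = (tc @ (Xm - Xm.mean(axis=0))) / denom
        # residual + prediction at sex-mean TEI == intake - slope*(tei - mean)
        out[m] = Xm - np.outer(tc, slopes)
    res = pd.DataFrame(out, index=frame.index, columns=frame.columns)
    if isinstance(values, pd.Series):
        return res.iloc[:, 0].rename(values.name)
    return res
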