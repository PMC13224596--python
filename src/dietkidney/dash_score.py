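"""Fung-style DASH adherence score with a tertile-ranked SSB component.

Eight energy-adjusted food components are ranked within sex into
sex-specific quantile categories: quintiles (ranks 1..5) for all
components except sugar-sweetened beverages (SSB), which — being sparsely
consumed in this population — are ranked into tertiles (1..3). "Healthy"
components (fruits, vegetables, whole grains, low-fat dairy,
nuts & legumes) score upward with intake; "unhealthy" components
(red/processed meat, sodium, SSB) score downward. The total score is the
sum of the eight ranks; the attainable minimum is 8 (worst diet on every
component) and the attainable maximum under this scheme is 38.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diet_processing import DASH_COMPONENTS

__all__ = ["rank_component", "total_dash", "score_dash"]

logger = logging.getLogger(__name__)

_SCHEME_K = {"quintile": 5, "tertile": 3}


def rank_component(values, sex, direction: str, scheme: str = "quintile"):
    """Rank one component's energy-adjusted intakes within sex.

    Empirical quantile cut-points (linear interpolation) are computed within
    each sex; category membership uses half-open intervals
    (-inf, c1], (c1, c2], ..., so ties at a cut-point fall in the lower
    category. For `direction="healthy"` the rank ascends with intake
    (1..k); for `"unhealthy"` it descends (k..1).

    Returns an integer array of ranks aligned with `values`.
    """
    if direction not in ("healthy", "unhealthy"):
        raise ValueError(f"direction must be healthy/unhealthy, got {direction!r}")
    k = _SCHEME_K[scheme]
    x = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    ranks = np.empty(x.shape, dtype=int)
    for s in np.unique(sex):
        m = sex == s
        if m.sum() < k:
            raise ValueError(f"need >= {k} subjects in sex {s} for {scheme} ranking")
        xs = x[m]
        cuts = np.quantile(xs, np.arange(1, k) / k)
        if np.ptp(xs) == 0:
            logger.warning("all-equal intakes in sex %s: every subject in category 1", s)
            cat = np.ones(xs.shape, dtype=int)
        else:
            # categories 1..k via (-inf, c1], (c1, c2], ...
            cat = np.searchsorted(cuts, xs, side="left") + 1
        ranks[m] = cat if direction == "healthy" else (k + 1 - cat)
    return ranks


def total_dash(ranks: pd.DataFrame) -> pd.Series:
    """Sum the 8 component ranks into the total DASH score per subject."""
    missing_cols = [c for c in DASH_COMPONENTS if c not in ranks.columns]
    if missing_cols:
        raise ValueError(f"missing DASH component rank columns: {missing_cols}")
    block = ranks[list(DASH_COMPONENTS)]
    if block.isna().any().any():
        bad = block.isna().any(axis=1)
        subj = block.index[bad][0]
        comp = block.columns[block.loc[subj].isna()][0]
        raise ValueError(f"missing rank for subject {subj!r}, component {comp!r}")
    return block.sum(axis=1).astype(int).rename("dash_total")


def score_dash(dash_components_adjusted: pd.DataFrame, sex) -> pd.DataFrame:
    """Rank all 8 components and total them.

    Parameters
    ----------
    dash_components_adjusted : energy-adjusted component intakes
        (columns named as in :data:`~dietkidney.diet_processing.DASH_COMPONENTS`).
    sex : array-like aligned with rows.

    Returns a DataFrame with one rank column per component (``rank_<name>``)
    plus ``dash_total``.
    """
    out = {}
    for comp, (direction, scheme) in DASH_COMPONENTS.items():
        out[comp] = rank_component(
            dash_components_adjusted[comp].to_numpy(), sex, direction, scheme
        )
    ranks = pd.DataFrame(out, index=dash_components_adjusted.index)
    total = total_dash(ranks)
    ranks = ranks.add_prefix("rank_")
    ranks["dash_total"] = total
    return ranks
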