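"""Reduced-rank regression (RRR) dietary-pattern engine.

Pipeline for deriving sex-specific dietary patterns from food-group
intakes and a panel of nine cardio-renal-metabolic mediator biomarkers
(HbA1c, mean arterial pressure, CRP, uric acid, total cholesterol,
ferritin, fibrinogen, serum potassium, haemoglobin):

1. quantile-normalize each mediator across assay batches onto the last
   (reference) batch, to remove measurement-method shifts;
2. residualize each mediator on age and a household random intercept
   (linear mixed model, REML), so patterns are not driven by age or shared
   household environment;
3. fit RRR of the adjusted mediators on the energy-adjusted, standardized
   food-group intakes: find linear combinations of food groups that
   maximize explained mediator variance (eigendecomposition of the fitted
   responses, computed via SVD);
4. choose the number of retained patterns by a scree rule;
5. score subjects by projecting standardized intakes on the predictor
   weights.

The mixed model is the standard random-intercept model
y = Xb + Z u + e, u ~ N(0, s_u^2), e ~ N(0, s_e^2), estimated by
one-dimensional optimization of the REML criterion profiled over the fixed
effects and the residual variance. Because households partition subjects,
all matrix algebra reduces to per-household closed forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import rankdata

__all__ = [
    "MEDIATORS",
    "RRRModel",
    "RandomInterceptFit",
    "quantile_normalize_batches",
    "fit_random_intercept",
    "reml_criterion",
    "adjust_mediators",
    "fit_rrr",
    "select_rank",
    "score_subjects",
]

logger = logging.getLogger(__name__)

#: mediator biomarkers used as RRR responses (name: unit)
MEDIATORS = {
    "hba1c": "%",
    "map": "mmHg",
    "crp": "mg/dL",
    "uric_acid": "mg/dL",
    "tc": "mg/dL",
    "ferritin": "ng/mL",
    "fibrinogen": "mg/dL",
    "potassium": "mmol/L",
    "hgb": "g/dL",
}


# ---------------------------------------------------------------------------
# Batch quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize_batches(values, batches, reference=None):
    """Map each batch's values onto the reference batch's quantile function.

    Each non-reference batch value is sent through its within-batch ecdf
    (average ranks, plotting positions (rank-1)/(n-1)) to the reference
    batch's empirical quantile function (linear interpolation). The
    reference batch (by default the last in sorted label order) passes
    through unchanged, and within-batch rank order is preserved.
    """
    x = np.asarray(values, dtype=float)
    b = np.asarray(batches)
    labels = sorted(pd.unique(b).tolist())
    ref = labels[-1] if reference is None else reference
    ref_vals = x[b == ref]
    if ref_vals.size == 0:
        raise ValueError(f"reference batch {ref!r} is empty")
    out = x.copy()
    for lab in labels:
        m = b == lab
        n = int(m.sum())
        if n == 0:
            raise ValueError(f"batch {lab!r} is empty")
        if lab == ref:
            continue
        if n < 2:
            raise ValueError(f"batch {lab!r} has < 2 values")
        p = (rankdata(x[m], method="average") - 1.0) / (n - 1.0)
        out[m] = np.quantile(ref_vals, p)
    return out


# ---------------------------------------------------------------------------
# Random-intercept mixed model (REML, profiled 1-d)
# ---------------------------------------------------------------------------

@dataclass
class RandomInterceptFit:
    """REML fit of y = Xb + Z u + e with a household random intercept."""

    beta: np.ndarray
    sigma_u2: float
    sigma_e2: float
    theta: float                 # variance ratio sigma_u2 / sigma_e2
    blup: dict                   # household -> predicted intercept
    adjusted: np.ndarray         # y - Xb - BLUP(u), exactly X-orthogonal
    criterion: float             # REML criterion at the optimum
    boundary: bool               # True if sigma_u2 pinned at 0


def _household_sums(values: np.ndarray, inverse: np.ndarray, n_groups: int):
    return np.bincount(inverse, weights=values, minlength=n_groups)


def reml_criterion(theta: float, y: np.ndarray, X: np.ndarray,
                   inverse: np.ndarray, sizes: np.ndarray):
    """Profiled REML criterion at variance ratio theta = s_u^2/s_e^2.

    Returns (criterion, beta, sigma_e2, V0inv_resid). The criterion is
    log|V0| + log|X' V0^-1 X| + (n-p) log(r' V0^-1 r) with V0 = I + theta ZZ',
    i.e. -2 log restricted likelihood up to an additive constant, profiled
    over the fixed effects and the residual variance.
    """
    n, p = X.shape
    shrink = theta / (1.0 + sizes * theta)          # per-household factor

    def v0inv(M):
        sums = np.stack(
            [_household_sums(M[:, j], inverse, sizes.size) for j in range(M.shape[1])],
            axis=1,
        )
        return M - (shrink[inverse, None] * sums[inverse])

    Xw = v0inv(X)
    yw = v0inv(y[:, None])[:, 0]
    XtVX = X.T @ Xw
    XtVy = Xw.T @ y
    beta = np.linalg.solve(XtVX, XtVy)
    r = y - X @ beta
    rw = v0inv(r[:, None])[:, 0]
    quad = float(r @ rw)
    logdet_v0 = float(np.sum(np.log1p(sizes * theta)))
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X' V0^-1 X not positive definite")
    crit = logdet_v0 + logdet_x + (n - p) * np.log(quad)
    return crit, beta, quad / (n - p), rw


def fit_random_intercept(y, X, household) -> RandomInterceptFit:
    """Fit the household random-intercept model by 1-d profiled REML.

    The variance ratio theta is optimized on the log scale with a bounded
    scalar minimizer; the boundary theta = 0 (no household variance) is
    checked explicitly and reported via ``boundary``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    hh = np.asarray(household)
    uniq, inverse = np.unique(hh, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 households for the random-intercept model")
    sizes = np.bincount(inverse).astype(float)

    def crit_of_log_theta(lt):
        return reml_criterion(np.exp(lt), y, X, inverse, sizes)[0]

    res = minimize_scalar(crit_of_log_theta, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"REML optimization failed: {res}")
    c0 = reml_criterion(0.0, y, X, inverse, sizes)[0]
    boundary = c0 <= res.fun
    theta = 0.0 if boundary else float(np.exp(res.x))
    if boundary:
        logger.info("household variance estimated at the zero boundary")
    crit, beta, sigma_e2, rw = reml_criterion(theta, y, X, inverse, sizes)
    # BLUP per household: theta * S_h / (1 + m_h * theta), S_h = sum of residuals
    r = y - X @ beta
    S = _household_sums(r, inverse, sizes.size)
    u = theta * S / (1.0 + sizes * theta)
    # adjusted = r - Z u = V0^-1 r  -> exactly orthogonal to the X columns
    adjusted = rw
    return RandomInterceptFit(
        beta=beta,
        sigma_u2=theta * sigma_e2,
        sigma_e2=sigma_e2,
        theta=theta,
        blup=dict(zip(uniq.tolist(), u.tolist())),
        adjusted=adjusted,
        criterion=float(crit),
        boundary=bool(boundary),
    )


def adjust_mediators(panel: pd.DataFrame, age, household,
                     subtract_blup: bool = True) -> pd.DataFrame:
    """Residualize each mediator on age and the household random intercept.

    For each mediator column, fits y = b0 + b1*age + u_household + e by REML
    and returns y - b0 - b1*age - BLUP(u) (default) or the fixed-effect-only
    residual y - b0 - b1*age when ``subtract_blup`` is False. With BLUP
    subtraction the adjusted values are exactly uncorrelated with age.

    Batch columns (``batch_*``) are ignored; run
    :func:`quantile_normalize_batches` first if batches are present.
    """
    age = np.asarray(age, dtype=float)
    if np.var(age) <= 0:
        raise ValueError("age variance must be positive")
    X = np.column_stack([np.ones_like(age), age])
    cols = [c for c in panel.columns if not c.startswith("batch_")]
    out = {}
    for c in cols:
        fit = fit_random_intercept(panel[c].to_numpy(dtype=float), X, household)
        if subtract_blup:
            out[c] = fit.adjusted
        else:
            out[c] = panel[c].to_numpy(dtype=float) - X @ fit.beta
    return pd.DataFrame(out, index=panel.index)


# ---------------------------------------------------------------------------
# Reduced-rank regression
# ---------------------------------------------------------------------------

@dataclass
class RRRModel:
    """Fitted reduced-rank regression of mediators on food groups."""

    sex: str
    x_columns: list
    y_columns: list
    x_mean: np.ndarray
    x_sd: np.ndarray
    predictor_weights: np.ndarray      # p x K (a_k columns)
    response_weights: np.ndarray       # q x K (v_k columns, unit norm)
    eigenvalues: np.ndarray            # all min(p, q), descending
    explained_variance_share: float    # first K patterns / total Y variance
    scores: pd.DataFrame               # training DP scores, n x K
    loadings: pd.DataFrame             # corr(food group, score), p x K
    rank: int = field(init=False)

    def __post_init__(self):
        self.rank = self.predictor_weights.shape[1]


def _standardize(M: np.ndarray, mean=None, sd=None):
    mean = M.mean(axis=0) if mean is None else mean
    sd = M.std(axis=0, ddof=1) if sd is None else sd
    if np.any(sd <= 0):
        raise ValueError("zero-variance column: cannot standardize")
    return (M - mean) / sd, mean, sd


def fit_rrr(X, Y, K: int = 2, sex: str = "all") -> RRRModel:
    """Reduced-rank regression of responses Y on predictors X.

    Both blocks are standardized column-wise (mean 0, SD 1). With
    B = (X'X)^-1 X'Y and fitted responses Yhat = XB, the k-th response
    weight v_k is the k-th right singular vector of Yhat (eigenvector of
    Yhat'Yhat), the predictor weight is a_k = B v_k, the pattern score is
    s_k = X a_k = Yhat v_k with eigenvalue lam_k = s_k's_k, and the share
    of total response variance explained by the first K patterns is
    sum_k lam_k / trace(Y'Y). Scores are pairwise orthogonal by
    construction. Signs are fixed so each a_k's largest-magnitude entry is
    positive.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    Ydf = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y))
    Xm = Xdf.to_numpy(dtype=float)
    Ym = Ydf.to_numpy(dtype=float)
    n, p = Xm.shape
    q = Ym.shape[1]
    if n <= p:
        raise ValueError(f"need n > p predictors (n={n}, p={p})")
    if not 1 <= K <= min(p, q):
        raise ValueError(f"rank K={K} outside 1..min(p, q)={min(p, q)}")
    Xs, x_mean, x_sd = _standardize(Xm)
    Ys, _, _ = _standardize(Ym)

    cond = np.linalg.cond(Xs.T @ Xs)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            "X'X is (near-)rank-deficient; drop or combine collinear food "
            "groups, or add an explicit ridge term upstream"
        )
    B, *_ = np.linalg.lstsq(Xs, Ys, rcond=None)
    Yhat = Xs @ B
    # SVD of the fitted responses instead of eigendecomposition of Yhat'Yhat
    U, svals, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eigenvalues = svals**2
    V = Vt.T[:, :K]
    A = B @ V
    # sign convention: largest-magnitude predictor weight positive
    for k in range(K):
        j = int(np.argmax(np.abs(A[:, k])))
        if A[j, k] < 0:
            A[:, k] = -A[:, k]
            V[:, k] = -V[:, k]
    scores = Xs @ A
    total_ss = float(np.sum(Ys**2))
    share = float(eigenvalues[:K].sum() / total_ss)

    # loadings: correlation of each (standardized) food group with each score
    sc_sd = scores.std(axis=0, ddof=1)
    load = (Xs - Xs.mean(0)).T @ (scores - scores.mean(0)) / (n - 1)
    load /= np.outer(Xs.std(axis=0, ddof=1), sc_sd)

    names = [f"dp{k + 1}" for k in range(K)]
    idx = Xdf.index
    return RRRModel(
        sex=sex,
        x_columns=list(Xdf.columns),
        y_columns=list(Ydf.columns),
        x_mean=x_mean,
        x_sd=x_sd,
        predictor_weights=A,
        response_weights=V,
        eigenvalues=eigenvalues,
        explained_variance_share=share,
        scores=pd.DataFrame(scores, index=idx, columns=names),
        loadings=pd.DataFrame(load, index=Xdf.columns, columns=names),
    )


def select_rank(eigenvalues, policy: str = "ratio", threshold: float = 0.10,
                cap: int = 2) -> int:
    """Automated stand-in for scree-plot inspection.

    ``policy="ratio"``: largest K with lam_K / lam_1 >= threshold, capped at
    ``cap`` (default 2, the rank used throughout the analysis).
    ``policy="fixed"``: always the cap (subject to availability). Falls back
    to K = 1 when nothing qualifies.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 2:
        return 1
    if policy == "fixed":
        return int(min(cap, lam.size))
    if policy != "ratio":
        raise ValueError(f"unknown rank policy {policy!r}")
    if lam[0] <= 0:
        return 1
    k = int(np.sum(lam / lam[0] >= threshold))
    return max(1, min(k, cap, lam.size))


def score_subjects(model: RRRModel, X_new) -> pd.DataFrame:
    """Project new subjects on a fitted model's predictor weights.

    ``X_new`` must carry exactly the training food-group columns; it is
    standardized with the *training* means and SDs, so applying the model
    to its own training matrix reproduces the training scores exactly.
    """
    Xdf = X_new if isinstance(X_new, pd.DataFrame) else pd.DataFrame(np.asarray(X_new))
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in model.x_columns if c not in Xdf.columns]
        extra = [c for c in Xdf.columns if c not in model.x_columns]
        if missing or extra:
            raise ValueError(
                f"food-group column mismatch: missing={missing}, extra={extra}"
            )
        Xdf = Xdf[model.x_columns]
    Xs = (Xdf.to_numpy(dtype=float) - model.x_mean) / model.x_sd
    scores = Xs @ model.predictor_weights
    names = [f"dp{k + 1}" for k in range(model.rank)]
    return pd.DataFrame(scores, index=Xdf.index, columns=names)
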