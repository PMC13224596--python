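"""Dietary-score / eGFR association models.

Implements the analysis layer: ordinary least squares on z-standardized
dietary scores with the fixed confounder set (age, TEI, physical activity,
smoking, education, BMI, special diet), additive models with penalized
regression splines for the score and age (smoothing parameters chosen by
REML), interaction models (score x menstrual status, score x age) in
females, and the full stratified analysis grid with the Healthy+
sensitivity repeat.

The smooth model is a Gaussian additive model

    eGFR = parametric covariates + f1(score) + f2(age) + error

where each f is a cubic B-spline expansion (default basis dimension 10,
knots at quantiles) with an integrated-squared-second-derivative penalty.
A sum-to-zero constraint absorbs each smooth's constant into the
intercept, leaving a one-dimensional penalty null space (the linear
function), so a smooth forced to infinite penalty collapses exactly onto
the linear model and its effective degrees of freedom (edf) go to 1. The
two penalties are optimized jointly on the log scale against the REML
criterion profiled over the coefficients and the error variance. The
smooth-term p-value is a Wald-type test on the penalized coefficients at
rank round(edf) — an approximation, reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from scipy.interpolate import BSpline
from scipy.optimize import minimize

__all__ = [
    "DEFAULT_COVARIATES",
    "AssociationResult",
    "z_standardize",
    "fit_linear",
    "SmoothTerm",
    "fit_smooth",
    "fit_interactions",
    "run_analysis_grid",
]

#: confounders of every association model (DAG-selected covariate list)
DEFAULT_COVARIATES = (
    "age",
    "tei",
    "physical_activity",
    "bmi",
    "smoking",
    "education",
    "special_diet",
)

_CATEGORICAL = {"smoking", "education", "special_diet"}


@dataclass
class AssociationResult:
    """One model cell: effect per 1-SD of a dietary score on eGFR."""

    exposure: str
    beta: float | None
    ci95: tuple | None
    p: float | None
    n: int
    edf: float | None = None
    smooth_p: float | None = None
    stratum: str | None = None
    model: str = "lm"
    extra: dict = field(default_factory=dict)


def z_standardize(x):
    """Center and scale to unit SD (ddof 1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValueError("cannot z-standardize a constant column")
    return (x - x.mean()) / sd


def _covariate_terms(covariates):
    return [f"C({c})" if c in _CATEGORICAL else c for c in covariates]


def _check_full_rank(exog, names):
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise ValueError(
            f"design matrix rank {rank} < {exog.shape[1]} columns; "
            f"collinear terms among {list(names)}"
        )


# ---------------------------------------------------------------------------
# Linear models
# ---------------------------------------------------------------------------

def fit_linear(data: pd.DataFrame, exposure: str, outcome: str = "egfr",
               covariates=DEFAULT_COVARIATES, stratum: str | None = None
               ) -> AssociationResult:
    """OLS of the outcome on the z-standardized exposure plus covariates.

    Categorical covariates are dummy-coded with the alphabetically first
    level as reference. The exposure is z-standardized within `data` (i.e.
    within the analysis stratum), so `beta` reads as ml/min/1.73 m² per
    1-SD of the score; the CI comes from the t distribution.
    """
    df = data.copy()
    df["_exposure_z"] = z_standardize(df[exposure])
    terms = ["_exposure_z"] + _covariate_terms([c for c in covariates if c in df])
    formula = f"{outcome} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df)
    _check_full_rank(model.exog, model.exog_names)
    fit = model.fit()
    ci = fit.conf_int().loc["_exposure_z"]
    return AssociationResult(
        exposure=exposure,
        beta=float(fit.params["_exposure_z"]),
        ci95=(float(ci[0]), float(ci[1])),
        p=float(fit.pvalues["_exposure_z"]),
        n=int(fit.nobs),
        stratum=stratum,
        model="lm",
        extra={"params": fit.params.to_dict()},
    )


# ---------------------------------------------------------------------------
# Penalized-spline smooth terms
# ---------------------------------------------------------------------------

@dataclass
class SmoothTerm:
    """Constrained cubic B-spline basis with a curvature penalty."""

    name: str
    basis: np.ndarray        # n x (k-1), sum-to-zero constrained
    penalty: np.ndarray      # (k-1) x (k-1), rank k-3 after constraint
    null_vector: np.ndarray  # penalty null direction (the linear function)
    knots: np.ndarray
    constraint: np.ndarray   # Z: k x (k-1) null basis of the constraint
    x_train: np.ndarray


def _bspline_design(x, knots, deriv=0):
    k = len(knots) - 4
    c = np.eye(k)
    cols = [BSpline(knots, c[j], 3).derivative(deriv)(x) if deriv
            else BSpline(knots, c[j], 3)(x) for j in range(k)]
    return np.column_stack(cols)


def make_smooth(x, name: str, k: int = 10) -> SmoothTerm:
    """Build a constrained penalized cubic B-spline basis for x.

    Interior knots sit at quantiles of x; the penalty is the exact
    integral of the squared second derivative (two-point Gauss rule per
    knot span, exact because the second derivative of a cubic spline is
    piecewise linear). A sum-to-zero constraint (column means removed via a
    null-space reparameterization) makes the basis identifiable next to an
    intercept; the penalty null space then contains only the linear
    function.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if k > n / 4:
        k = max(5, int(n / 4))
    n_interior = k - 4
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError(f"smooth term {name!r}: x has no spread")
    interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
    interior = np.clip(interior, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
    knots = np.r_[[lo] * 4, np.sort(interior), [hi] * 4]

    B = _bspline_design(x, knots)

    # exact curvature penalty via 2-point Gauss per span
    spans = np.unique(knots)
    gp, gw = np.polynomial.legendre.leggauss(2)
    S = np.zeros((k, k))
    for a, b in zip(spans[:-1], spans[1:]):
        if b <= a:
            continue
        mid, half = (a + b) / 2.0, (b - a) / 2.0
        pts = mid + half * gp
        D2 = _bspline_design(pts, knots, deriv=2)
        S += half * (D2.T * gw) @ D2

    # sum-to-zero constraint: 1'B beta = 0 -> beta = Z gamma
    Csum = B.sum(axis=0, keepdims=True)
    q, _ = np.linalg.qr(Csum.T, mode="complete")
    Z = q[:, 1:]
    Bz = B @ Z
    Sz = Z.T @ S @ Z
    Sz = (Sz + Sz.T) / 2.0

    w, vec = np.linalg.eigh(Sz)
    null_vector = vec[:, 0]  # smallest eigenvalue ~ 0: the linear direction
    return SmoothTerm(name=name, basis=Bz, penalty=Sz, null_vector=null_vector,
                      knots=knots, constraint=Z, x_train=x)


def _smooth_reml_fit(y, P, smooths, log_lams):
    """Penalized LS fit at fixed log smoothing parameters.

    Returns (criterion, beta, XtXpS_inv, X, sigma2, col_slices).
    """
    n = y.size
    blocks = [P] + [s.basis for s in smooths]
    X = np.column_stack(blocks)
    ncols = X.shape[1]
    col_slices = []
    start = P.shape[1]
    for s in smooths:
        kk = s.basis.shape[1]
        col_slices.append(slice(start, start + kk))
        start += kk
    S = np.zeros((ncols, ncols))
    rank_sum_log = 0.0
    for s, sl, ll in zip(smooths, col_slices, log_lams):
        lam = np.exp(ll)
        S[sl, sl] += lam * s.penalty
        r = s.penalty.shape[0] - 1  # penalty rank (one-dim null space)
        rank_sum_log += r * ll
    XtX = X.T @ X
    A = XtX + S
    beta = np.linalg.solve(A, X.T @ y)
    resid = y - X @ beta
    D = float(resid @ resid + beta @ S @ beta)
    m_null = P.shape[1] + len(smooths)  # unpenalized dimensions
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("penalized normal matrix not PD")
    crit = (n - m_null) * np.log(D) + logdet_a - rank_sum_log
    sigma2 = D / (n - m_null)
    return crit, beta, A, X, sigma2, col_slices, XtX


def fit_smooth(data: pd.DataFrame, exposure: str, outcome: str = "egfr",
               covariates=DEFAULT_COVARIATES, k: int = 10,
               stratum: str | None = None,
               force_linear: bool = False) -> AssociationResult:
    """Additive model: smooth(exposure) + smooth(age) + linear covariates.

    Smoothing parameters for both penalized splines are selected jointly by
    minimizing the profiled REML criterion over log-lambda. `force_linear`
    replaces each smooth by its penalty null space (the linear function),
    i.e. the exact infinite-penalty limit, in which the fit coincides with
    the ordinary linear model.

    The reported `edf` is the effective degrees of freedom of the exposure
    smooth (trace of its block of the influence matrix); `smooth_p` is the
    approximate Wald test of the exposure smooth's coefficients.
    """
    df = data.copy()
    df["_exposure_z"] = z_standardize(df[exposure])
    y = df[outcome].to_numpy(dtype=float)

    # parametric block: intercept + covariates except age (age gets a smooth)
    par_covs = [c for c in covariates if c in df.columns and c != "age"]
    terms = _covariate_terms(par_covs)
    rhs = " + ".join(terms) if terms else "1"
    P = smf.ols(f"{outcome} ~ {rhs}", data=df).exog
    smooths = [make_smooth(df["_exposure_z"].to_numpy(), "s(exposure)", k=k)]
    has_age = "age" in covariates and "age" in df.columns
    if has_age:
        smooths.append(make_smooth(df["age"].to_numpy(dtype=float), "s(age)", k=k))

    if force_linear:
        # infinite-penalty limit: each smooth contributes only its linear part
        lin_cols = [s.basis @ s.null_vector for s in smooths]
        X = np.column_stack([P] + [c[:, None] for c in lin_cols])
        _check_full_rank(X, range(X.shape[1]))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid = y - fitted
        dof = y.size - X.shape[1]
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        j = P.shape[1]  # exposure linear column
        se = np.sqrt(cov[j, j])
        tval = beta[j] / se
        p = 2 * stats.t.sf(abs(tval), dof)
        return AssociationResult(
            exposure=exposure, beta=None, ci95=None, p=None, n=y.size,
            edf=1.0, smooth_p=float(p), stratum=stratum, model="gam",
            extra={"fitted": fitted, "forced_linear": True},
        )

    n_lam = len(smooths)

    def crit(log_lams):
        # clip keeps exp(lam) finite while the simplex explores the plateau
        log_lams = np.clip(log_lams, -25.0, 25.0)
        try:
            c = _smooth_reml_fit(y, P, smooths, log_lams)[0]
        except np.linalg.LinAlgError:
            return np.inf
        return c if np.isfinite(c) else np.inf

    # coarse grid start, then Nelder-Mead on log-lambda
    grid = np.arange(-6.0, 16.1, 2.0)
    if n_lam == 1:
        start = np.array([min(grid, key=lambda g: crit([g]))])
    else:
        best, start = np.inf, np.zeros(n_lam)
        for g1 in grid:
            for g2 in grid:
                c = crit([g1, g2])
                if c < best:
                    best, start = c, np.array([g1, g2])
    res = minimize(crit, start, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"REML optimization for smoothing parameters failed: {res}")
    log_lams = np.clip(res.x, -25.0, 25.0)
    _, beta, A, X, sigma2, col_slices, XtX = _smooth_reml_fit(y, P, smooths, log_lams)

    Ainv = np.linalg.inv(A)
    F = Ainv @ XtX  # influence map on coefficients
    sl = col_slices[0]
    edf = float(np.trace(F[sl, sl]))
    edfs = [float(np.trace(F[s_, s_])) for s_ in col_slices]

    # approximate Wald test on the exposure smooth's penalized coefficients
    Vb = sigma2 * (Ainv @ XtX @ Ainv)
    bj = beta[sl]
    Vj = Vb[sl, sl]
    r = max(1, int(round(edf)))
    w, vec = np.linalg.eigh(Vj)
    order = np.argsort(w)[::-1]
    w, vec = w[order[:r]], vec[:, order[:r]]
    tstat = float(np.sum((vec.T @ bj) ** 2 / w))
    smooth_p = float(stats.chi2.sf(tstat, df=r))

    fitted = X @ beta
    return AssociationResult(
        exposure=exposure, beta=None, ci95=None, p=None, n=y.size,
        edf=edf, smooth_p=smooth_p, stratum=stratum, model="gam",
        extra={
            "fitted": fitted,
            "log_lambda": log_lams.tolist(),
            "edf_age": edfs[1] if has_age else None,
            "sigma2": sigma2,
        },
    )


def plot_fitted_vs_score(data: pd.DataFrame, exposure: str, fitted, path,
                         outcome: str = "egfr", n_bins: int = 25):
    """Diagnostic plot: model-predicted outcome against the z-scored exposure.

    Draws the observed outcome (thinned scatter) and the binned mean of the
    model's fitted values, i.e. the shape the smooth term actually fit.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = z_standardize(data[exposure])
    fitted = np.asarray(fitted, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    keep = slice(None, None, max(1, len(z) // 2000))
    ax.plot(z[keep], data[outcome].to_numpy()[keep], ".", ms=2, alpha=0.25,
            color="grey", label="observed")
    bins = np.quantile(z, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(bins, z, side="right") - 1, 0, n_bins - 1)
    centers = [z[idx == b].mean() for b in range(n_bins) if (idx == b).any()]
    means = [fitted[idx == b].mean() for b in range(n_bins) if (idx == b).any()]
    ax.plot(centers, means, "-", lw=2, color="crimson", label="predicted")
    ax.set_xlabel(f"{exposure} (per 1 SD)")
    ax.set_ylabel(f"predicted {outcome}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Interaction models (females)
# ---------------------------------------------------------------------------

def fit_interactions(data: pd.DataFrame, scores, modifier: str = "menstrual_status",
                     outcome: str = "egfr", covariates=DEFAULT_COVARIATES,
                     modifier_reference: str | None = "yes") -> pd.DataFrame:
    """Score x menstrual-status and score x age interaction models (females).

    One OLS model per score, containing the z-standardized score, its
    interaction with the modifier and with age, plus main effects and the
    confounders. The modifier's reference level defaults to "yes"
    (still-menstruating), so the reported interaction coefficient is the
    *additional* effect per 1-SD of the score in the ceased-menstruation
    stratum; pass ``modifier_reference=None`` for the alphabetical default.
    Returns one row per score with the modifier interaction coefficient, CI
    and p, and the age-interaction p.
    """
    df = data.copy()
    if modifier not in df.columns:
        raise ValueError(f"modifier column {modifier!r} missing")
    if df[modifier].nunique() < 2:
        raise ValueError(f"modifier {modifier!r} has a single level in the data")
    if modifier_reference is None:
        mod_term = f"C({modifier})"
    else:
        mod_term = f"C({modifier}, Treatment({modifier_reference!r}))"
    rows = []
    cov_terms = _covariate_terms([c for c in covariates if c in df.columns])
    for score in np.atleast_1d(scores):
        df["_exposure_z"] = z_standardize(df[score])
        formula = (
            f"{outcome} ~ _exposure_z * {mod_term} + _exposure_z:age + "
            + " + ".join(cov_terms)
        )
        model = smf.ols(formula, data=df)
        _check_full_rank(model.exog, model.exog_names)
        fit = model.fit()
        iname = [nm for nm in fit.params.index
                 if nm.startswith("_exposure_z:C(")][0]
        ci = fit.conf_int().loc[iname]
        rows.append({
            "score": score,
            "interaction_term": iname,
            "beta_interaction": float(fit.params[iname]),
            "ci_lo": float(ci[0]),
            "ci_hi": float(ci[1]),
            "p_interaction": float(fit.pvalues[iname]),
            "p_age_interaction": float(fit.pvalues["_exposure_z:age"]),
            "n": int(fit.nobs),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full stratified grid
# ---------------------------------------------------------------------------

_STRATA = {
    "males": lambda d: d["sex"] == "male",
    "females": lambda d: d["sex"] == "female",
    "menstruation_yes": lambda d: (d["sex"] == "female") & (d["menstrual_status"] == "yes"),
    "menstruation_no": lambda d: (d["sex"] == "female") & (d["menstrual_status"] == "no"),
}


def run_analysis_grid(data: pd.DataFrame, scores=("dash_total", "dp1", "dp2"),
                      outcome: str = "egfr", covariates=DEFAULT_COVARIATES,
                      healthy_plus_mask=None, smooth_k: int = 10) -> pd.DataFrame:
    """Run {scores} x {LM, GAM} x {strata}, optionally repeated on Healthy+.

    `data` must contain the outcome, the score columns, `sex`,
    `menstrual_status`, and the covariates. `healthy_plus_mask` (True =
    exclude) triggers the sensitivity repeat. Failures in individual cells
    are recorded in the `error` column and do not stop the grid.
    """
    samples = {"main": data}
    if healthy_plus_mask is not None:
        samples["healthy_plus"] = data.loc[~np.asarray(healthy_plus_mask)]
    rows = []
    for sample_name, d in samples.items():
        for stratum, selector in _STRATA.items():
            sub = d.loc[selector(d)]
            for score in scores:
                for model_kind in ("lm", "gam"):
                    row = {"sample": sample_name, "stratum": stratum,
                           "score": score, "model": model_kind}
                    try:
                        if model_kind == "lm":
                            r = fit_linear(sub, score, outcome, covariates, stratum)
                            row.update(beta=r.beta, ci_lo=r.ci95[0],
                                       ci_hi=r.ci95[1], p=r.p, n=r.n)
                        else:
                            r = fit_smooth(sub, score, outcome, covariates,
                                           k=smooth_k, stratum=stratum)
                            row.update(edf=r.edf, smooth_p=r.smooth_p, n=r.n)
                        row["error"] = None
                    except Exception as exc:  # cell-level failure: record, continue
                        row["error"] = f"{type(exc).__name__}: {exc}"
                    rows.append(row)
    cols = ["sample", "stratum", "score", "model", "beta", "ci_lo", "ci_hi",
            "p", "edf", "smooth_p", "n", "error"]
    out = pd.DataFrame(rows)
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    return out[cols]
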