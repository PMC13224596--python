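"""End-to-end pipeline orchestration.

Runs generate -> prep -> diet -> dash -> rrr -> associate from a single
YAML-able configuration, writing every stage's artifacts plus a manifest
(seed, configuration echo, SHA-256 of each output) into a run directory.
Re-running with an identical configuration reproduces identical numeric
outputs. A single seed fans out to per-stage use through the generator's
own stream; no stage draws randomness outside the generator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, cohort_prep, dash_score, diet_processing, rrr_engine
from .synthetic_cohort import CohortConfig, SyntheticCohort, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "validate_config", "run_pipeline",
           "prepare_sample", "derive_scores", "attach_scores"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Top-level run configuration (YAML-serializable)."""

    seed: int = 0
    out_dir: str = "run"
    n_subjects: int = 5000
    cohort: dict = field(default_factory=dict)       # CohortConfig overrides
    bmr_equation: str = "schofield"
    rank_policy: str = "ratio"                       # or "fixed" (always K=2)
    rank_threshold: float = 0.10
    rank_cap: int = 2
    healthy_plus: bool = True
    subtract_blup: bool = True
    smooth_k: int = 10
    plots: bool = False
    stages: dict = field(default_factory=lambda: {
        "generate": True, "prep": True, "diet": True,
        "dash": True, "rrr": True, "associate": True})

    def cohort_config(self) -> CohortConfig:
        kw = dict(self.cohort)
        kw.setdefault("n_subjects", self.n_subjects)
        kw.setdefault("seed", self.seed)
        return CohortConfig(**kw)


def validate_config(path) -> PipelineConfig:
    """Load and schema-check a YAML pipeline config; echo filled defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    problems = [f"unknown key: {k!r}" for k in raw if k not in known]
    cfg = None
    if not problems:
        cfg = PipelineConfig(**raw)
        if cfg.n_subjects <= 0:
            problems.append("n_subjects: must be positive")
        if cfg.rank_policy not in ("ratio", "fixed"):
            problems.append(f"rank_policy: unknown policy {cfg.rank_policy!r}")
        if not 0 < cfg.rank_threshold <= 1:
            problems.append("rank_threshold: must lie in (0, 1]")
        if cfg.rank_cap < 1:
            problems.append("rank_cap: must be >= 1")
        try:
            cfg.cohort_config()
        except (TypeError, ValueError) as exc:
            problems.append(f"cohort: {exc}")
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))
    logger.info("validated config: %s", dataclasses.asdict(cfg))
    return cfg


# ---------------------------------------------------------------------------
# Stage helpers (also used directly by tests and the acceptance script)
# ---------------------------------------------------------------------------

def prepare_sample(cohort: SyntheticCohort):
    """Exclusion cascade + eGFR + menstrual imputation + fallback imputation.

    Returns (tables dict, exclusion report). The covariates table gains an
    `egfr` column and an imputed `menstrual_status`.
    """
    tables, report = cohort_prep.apply_exclusions(cohort)
    cov = tables["covariates"]
    scr = tables["creatinine"].set_index("subject_id").loc[
        cov["subject_id"], "creatinine"].to_numpy()
    cov["egfr"] = cohort_prep.compute_egfr(scr, cov["age"].to_numpy(),
                                           cov["sex"].to_numpy())
    fem = cov["sex"] == "female"
    cov.loc[fem, "menstrual_status"] = cohort_prep.impute_menstrual_status(
        cov.loc[fem, "menstrual_status"].to_numpy(), cov.loc[fem, "age"].to_numpy())
    med_cols = list(rrr_engine.MEDIATORS)
    tables["biomarkers"][med_cols] = cohort_prep.simple_impute(
        tables["biomarkers"][med_cols])
    tables["covariates"] = cov
    return tables, report


def derive_scores(tables, rank_policy="ratio", rank_threshold=0.10, rank_cap=2,
                  subtract_blup=True):
    """Diet matrix, DASH score and sex-specific RRR patterns.

    Returns (diet matrix, dash table, {sex: RRRModel}, combined scores frame).
    """
    cov = tables["covariates"].set_index("subject_id")
    ffq = tables["ffq"]
    diet = diet_processing.build_diet_matrix(ffq, tables["composition"])
    sex = cov.loc[diet.group_intake.index, "sex"].to_numpy()
    tei = diet.tei.to_numpy()
    diet.group_intake_adjusted = diet_processing.energy_adjust(
        diet.group_intake, tei, sex)
    diet.dash_components_adjusted = diet_processing.energy_adjust(
        diet.dash_components, tei, sex)

    dash = dash_score.score_dash(diet.dash_components_adjusted, sex)

    bio = tables["biomarkers"].set_index("subject_id").loc[diet.group_intake.index]
    age = cov.loc[diet.group_intake.index, "age"].to_numpy()
    household = cov.loc[diet.group_intake.index, "household_id"].to_numpy()

    models, score_frames = {}, []
    for s in ("male", "female"):
        m = sex == s
        panel = bio.loc[m, list(rrr_engine.MEDIATORS)].copy()
        for name in rrr_engine.MEDIATORS:
            bcol = f"batch_{name}"
            if bcol in bio.columns:
                panel[name] = rrr_engine.quantile_normalize_batches(
                    panel[name].to_numpy(), bio.loc[m, bcol].to_numpy())
        adj = rrr_engine.adjust_mediators(panel, age[m], household[m],
                                          subtract_blup=subtract_blup)
        X = diet.group_intake_adjusted.loc[m]
        informative = X.std(ddof=1) > 0
        if not informative.all():
            logger.info("dropping %d zero-variance food groups in %s stratum",
                        int((~informative).sum()), s)
            X = X.loc[:, informative]
        full = rrr_engine.fit_rrr(X, adj, K=min(9, X.shape[1]), sex=s)
        K = (2 if rank_policy == "fixed"
             else rrr_engine.select_rank(full.eigenvalues, rank_policy,
                                         rank_threshold, rank_cap))
        model = rrr_engine.fit_rrr(X, adj, K=K, sex=s)
        models[s] = model
        score_frames.append(model.scores)
    scores = pd.concat(score_frames).loc[diet.group_intake.index]
    return diet, dash, models, scores


def attach_scores(tables, diet, dash, scores) -> pd.DataFrame:
    """Analysis frame: covariates + eGFR + dash_total + dp scores."""
    cov = tables["covariates"].set_index("subject_id")
    df = cov.copy()
    df["dash_total"] = dash["dash_total"]
    for c in scores.columns:
        df[c] = scores[c]
    df["tei"] = diet.tei
    return df.reset_index()


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all enabled stages in fixed order; return the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "config": dataclasses.asdict(config),
                "outputs": {}}
    stage = "generate"
    try:
        cohort_dir = run_dir / "cohort"
        cohort_dir.mkdir(exist_ok=True)
        cohort = generate_cohort(config.cohort_config())
        if config.stages.get("generate", True):
            write_cohort(cohort, cohort_dir)

        stage = "prep"
        tables, report = prepare_sample(cohort)
        tables["covariates"].to_csv(run_dir / "analysis_sample.csv", index=False)
        (run_dir / "exclusion_report.json").write_text(
            json.dumps(report.to_dict(), indent=1))

        stage = "diet"
        diet, dash, models, scores = derive_scores(
            tables, config.rank_policy, config.rank_threshold, config.rank_cap,
            config.subtract_blup)
        diet_out = pd.concat(
            [diet.group_intake, diet.dash_components,
             diet.tei.rename("tei")], axis=1)
        diet_out.to_csv(run_dir / "diet_matrix.csv")

        stage = "dash"
        dash.to_csv(run_dir / "dash_scores.csv")

        stage = "rrr"
        for s, model in models.items():
            (run_dir / f"rrr_model_{s}.json").write_text(json.dumps({
                "sex": s,
                "rank": model.rank,
                "x_columns": model.x_columns,
                "y_columns": list(model.y_columns),
                "predictor_weights": model.predictor_weights.tolist(),
                "response_weights": model.response_weights.tolist(),
                "eigenvalues": model.eigenvalues.tolist(),
                "explained_variance_share": model.explained_variance_share,
            }, indent=1))
            model.loadings.to_csv(run_dir / f"loadings_{s}.tsv", sep="\t")
            scree = pd.DataFrame({
                "component": np.arange(1, model.eigenvalues.size + 1),
                "eigenvalue": model.eigenvalues,
                "ratio_to_first": model.eigenvalues / model.eigenvalues[0],
            })
            scree.to_csv(run_dir / f"scree_{s}.tsv", sep="\t", index=False)
        scores.to_csv(run_dir / "rrr_scores.csv")

        stage = "associate"
        df = attach_scores(tables, diet, dash, scores)
        hp_mask = None
        if config.healthy_plus:
            bio = tables["biomarkers"].set_index("subject_id").loc[df["subject_id"]]
            hp_mask = cohort_prep.flag_healthy_plus(
                bio["hba1c"], df["egfr"], df["uacr"])
        results = association.run_analysis_grid(
            df, healthy_plus_mask=hp_mask, smooth_k=config.smooth_k)
        results.to_csv(run_dir / "results.tsv", sep="\t", index=False)
        (run_dir / "table2_report.md").write_text(_table2_report(results))
        if config.plots:
            _diagnostic_plots(df, run_dir / "plots", smooth_k=config.smooth_k)
    except Exception:
        manifest["failed_stage"] = stage
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.exception("pipeline halted at stage %s", stage)
        raise

    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(run_dir))] = _sha256(p)
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return run_dir


def _diagnostic_plots(df, plot_dir: Path, smooth_k: int = 10):
    """Predicted-eGFR-vs-score plots for each main-grid smooth model."""
    plot_dir.mkdir(exist_ok=True)
    for stratum, selector in association._STRATA.items():
        sub = df.loc[selector(df)]
        for score in ("dash_total", "dp1", "dp2"):
            try:
                r = association.fit_smooth(sub, score, k=smooth_k,
                                           stratum=stratum)
                association.plot_fitted_vs_score(
                    sub, score, r.extra["fitted"],
                    plot_dir / f"gam_{stratum}_{score}.png")
            except Exception:
                logger.exception("plot failed for %s/%s", stratum, score)


_SCORE_LABEL = {"dash_total": "DASH", "dp1": "DP1", "dp2": "DP2"}


def _table2_report(results: pd.DataFrame) -> str:
    """Markdown report shaped like the stratified LM/GAM results table."""
    lines = ["# Dietary scores vs eGFR — stratified results", ""]
    for sample in results["sample"].unique():
        lines += [f"## Sample: {sample}", "",
                  "| Stratum | Score | LM effect (95% CI) | LM p | edf | GAM p |",
                  "|---|---|---|---|---|---|"]
        sub = results[results["sample"] == sample]
        for stratum in sub["stratum"].unique():
            for score in sub["score"].unique():
                lm = sub[(sub.stratum == stratum) & (sub.score == score)
                         & (sub.model == "lm")]
                gam = sub[(sub.stratum == stratum) & (sub.score == score)
                          & (sub.model == "gam")]
                if lm.empty:
                    continue
                lm, gam = lm.iloc[0], (gam.iloc[0] if not gam.empty else None)
                if lm["error"]:
                    cell = f"failed: {lm['error']}"
                    lines.append(f"| {stratum} | {_SCORE_LABEL.get(score, score)} "
                                 f"| {cell} | | | |")
                    continue
                eff = (f"{lm.beta:.2f} ({lm.ci_lo:.2f}, {lm.ci_hi:.2f})")
                edf = f"{gam.edf:.2f}" if gam is not None and not gam["error"] else "—"
                gp = f"{gam.smooth_p:.4f}" if gam is not None and not gam["error"] else "—"
                lines.append(
                    f"| {stratum} | {_SCORE_LABEL.get(score, score)} | {eff} "
                    f"| {lm.p:.4f} | {edf} | {gp} |")
        lines.append("")
    return "\n".join(lines)
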