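"""End-to-end orchestration of the observational and heterogeneity analyses.

``compute_block_metrics`` reduces a survey to one row per block (diversity
at three scales, µ/σ/CV of biomass, species covariation, environmental
heterogeneity).  ``run_observational`` chains the bivariate mixed fits,
the RMA robustness fits, climate residualization, and the piecewise SEM;
``run_heterogeneity`` compares matched pre/post phases (phase effects,
diversity x heterogeneity interactions, multigroup SEM).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .diversity import (
    BlockCoverMatrix,
    UndefinedPlotError,
    alpha_diversity,
    beta_additive,
    beta_jaccard_dispersion,
    beta_whittaker,
    gamma_diversity,
)
from .inference import (
    climate_residualize,
    fit_mixed,
    heterogeneity_interaction,
    rma_fit,
    treatment_effects,
)
from .io import SurveyDataset, validate_design, write_block_metrics
from .sem import DagSpec, fit_sem, multigroup_sem
from .stability import (
    UndefinedMetricError,
    environmental_heterogeneity,
    spatial_variability,
    species_biomass,
    species_covariation,
    standardize_soil,
)

__all__ = [
    "RunConfig",
    "compute_block_metrics",
    "observational_dag",
    "run_observational",
    "run_heterogeneity",
]

DIVERSITY_SCALES = ("alpha", "beta_disp", "gamma")


@dataclass
class RunConfig:
    """Knobs shared by the pipeline entry points."""

    covariation_variant: str = "squared"  # or "as_printed"
    beta_metric: str = "jaccard"  # or "ruzicka"
    diversity_index: str = "richness"
    whittaker_convention: str = "as_printed"
    test: str = "lrt"  # or "wald"
    simplify_sem: bool = False
    out_dir: Optional[str] = None
    seed: int = 0


def observational_dag(with_env_het: bool = False) -> DagSpec:
    """The packaged initial path diagram (optionally with the soil-
    heterogeneity node acting on beta-diversity)."""
    text = (
        resources.files("divstab").joinpath("configs/observational_dag.txt").read_text()
    )
    dag = DagSpec.from_text(text)
    if with_env_het:
        dag = DagSpec(
            nodes=(*dag.nodes, "env_het"),
            edges=(*dag.edges, ("env_het", "beta_disp")),
            correlated=dag.correlated,
            grouping=dag.grouping,
        )
    return dag


def _block_cover_matrix(block_cover: pd.DataFrame, plot_ids: list) -> BlockCoverMatrix:
    if len(block_cover) == 0:
        mat = np.zeros((len(plot_ids), 0))
        return BlockCoverMatrix(plot_ids, [], mat)
    pivot = (
        block_cover.pivot_table(
            index="plot_id", columns="taxon", values="cover", aggfunc="sum", fill_value=0.0
        )
        .reindex(plot_ids, fill_value=0.0)
    )
    return BlockCoverMatrix(list(pivot.index), list(pivot.columns), pivot.to_numpy(dtype=float))


def compute_block_metrics(
    data: SurveyDataset, cfg: Optional[RunConfig] = None
) -> tuple[pd.DataFrame, dict]:
    """One metric row per block, plus an exclusion/flag report.

    Blocks with fewer than two plots are skipped entirely; blocks where a
    statistic is undefined (all-zero species spreads, zero CV on the log
    scale, plots with no species) get NaN for that statistic and are
    counted in the exclusions dict.
    """
    cfg = cfg or RunConfig()
    soil_z = None
    if data.soil is not None:
        try:
            soil_z = standardize_soil(data.soil)
        except ValueError as exc:
            warnings.warn(f"soil heterogeneity unavailable: {exc}")
    rows = []
    exclusions = {
        "blocks_lt2_plots": 0,
        "covariation_undefined": 0,
        "log_cv_undefined": 0,
        "beta_undefined": 0,
        "diversity_undefined": 0,
    }
    soil_groups = (
        dict(tuple(soil_z.groupby(["site_id", "block_id"]))) if soil_z is not None else {}
    )
    for site, block, bm, cv_long, _ in data.iter_blocks():
        plot_ids = list(bm["plot_id"])
        if len(plot_ids) < 2:
            exclusions["blocks_lt2_plots"] += 1
            continue
        m = _block_cover_matrix(cv_long, plot_ids)
        biomass = bm["live_biomass_g_m2"].to_numpy(dtype=float)
        row = {"site_id": site, "block_id": block, "n_plots": len(plot_ids)}

        try:
            row["alpha"] = alpha_diversity(m, cfg.diversity_index)
            row["gamma"] = gamma_diversity(m, cfg.diversity_index)
        except UndefinedPlotError:
            exclusions["diversity_undefined"] += 1
            row["alpha"] = row["gamma"] = np.nan
        try:
            row["beta_disp"] = beta_jaccard_dispersion(m, metric=cfg.beta_metric)
        except (UndefinedPlotError, ValueError):
            exclusions["beta_undefined"] += 1
            row["beta_disp"] = np.nan
        if np.isfinite(row.get("alpha", np.nan)) and row.get("alpha", 0) > 0:
            row["beta_whittaker"] = beta_whittaker(
                row["alpha"], row["gamma"], cfg.whittaker_convention
            )
            row["beta_additive"] = beta_additive(row["alpha"], row["gamma"])
        else:
            row["beta_whittaker"] = row["beta_additive"] = np.nan

        try:
            stab = spatial_variability(biomass)
            row.update(mu=stab.mu, sigma=stab.sigma, cv=stab.cv, log_cv=stab.log_cv)
            if not np.isfinite(stab.log_cv):
                exclusions["log_cv_undefined"] += 1
        except UndefinedMetricError:
            exclusions["log_cv_undefined"] += 1
            row.update(mu=float(np.mean(biomass)), sigma=np.nan, cv=np.nan, log_cv=np.nan)

        try:
            sb = species_biomass(m, biomass)
            row["covariation"] = species_covariation(sb, variant=cfg.covariation_variant)
        except (UndefinedMetricError, ValueError):
            exclusions["covariation_undefined"] += 1
            row["covariation"] = np.nan

        if soil_groups:
            sgrp = soil_groups.get((site, block))
            if sgrp is not None and len(sgrp) >= 2:
                svars = [c for c in sgrp.columns if c not in ("site_id", "block_id", "plot_id")]
                row["env_het"] = environmental_heterogeneity(sgrp[svars].to_numpy(dtype=float))
            else:
                row["env_het"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows), exclusions


def _bivariate_rows(metrics: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    pairs = [("log_cv", p) for p in DIVERSITY_SCALES]
    pairs += [("covariation", p) for p in DIVERSITY_SCALES]
    pairs += [("log_cv", "covariation")]
    pairs += [("mu", p) for p in DIVERSITY_SCALES]
    pairs += [("sigma", p) for p in DIVERSITY_SCALES]
    rows = []
    for resp, pred in pairs:
        sub = metrics[["site_id", resp, pred]].dropna()
        base = {"response": resp, "predictor": pred, "n_obs": len(sub)}
        try:
            r = fit_mixed(sub[resp], sub[pred], sub["site_id"], test=cfg.test)
            rows.append(
                base
                | {
                    "slope": r.slope,
                    "ci_lo": r.ci95[0],
                    "ci_hi": r.ci95[1],
                    "chi2": r.chi2,
                    "p": r.p,
                    "random_structure": r.random_structure,
                    "n_groups": r.n_groups,
                    "note": r.notes,
                }
            )
        except ValueError as exc:
            rows.append(base | {"slope": np.nan, "note": str(exc)})
    return pd.DataFrame(rows)


def _rma_rows(metrics: pd.DataFrame, response: str = "log_cv") -> pd.DataFrame:
    site_means = metrics.groupby("site_id")[[response, *DIVERSITY_SCALES]].mean()
    rows = []
    for pred in DIVERSITY_SCALES:
        sub = site_means[[response, pred]].dropna()
        try:
            r = rma_fit(sub[pred], sub[response])
            rows.append(
                {
                    "response": response,
                    "predictor": pred,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "ci_lo": r.ci95[0],
                    "ci_hi": r.ci95[1],
                    "n_sites": r.n,
                }
            )
        except ValueError as exc:
            rows.append({"response": response, "predictor": pred, "slope": np.nan, "note": str(exc)})
    return pd.DataFrame(rows)


def _sem_summary(sem) -> dict:
    return {
        "fisher_c": sem.fisher_c,
        "dsep_df": sem.dsep_df,
        "dsep_p": sem.dsep_p,
        "r2": {k: {"marginal": v[0], "conditional": v[1]} for k, v in sem.r2.items()},
        "n_obs": sem.n_obs,
        "dropped_paths": [
            {"edge": list(d["edge"]), "p_at_drop": d["p_at_drop"]} for d in sem.dropped_paths
        ],
        "edges": [list(e) for e in sem.dag.edges],
    }


def _run_log(cfg: RunConfig, design, exclusions: dict) -> dict:
    import scipy
    import statsmodels

    return {
        "seed": cfg.seed,
        "covariation_variant": cfg.covariation_variant,
        "beta_metric": cfg.beta_metric,
        "diversity_index": cfg.diversity_index,
        "test": cfg.test,
        "versions": {
            "divstab": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "design": {
            "n_sites": design.n_sites,
            "n_blocks": design.n_blocks,
            "n_plots": design.n_plots,
            "excluded_blocks": [list(b) for b in design.excluded_blocks],
            "non_canonical_blocks": len(design.warning_blocks),
        },
        "exclusions": exclusions,
    }


def run_observational(data: SurveyDataset, cfg: Optional[RunConfig] = None) -> dict:
    """The observational (pre-treatment) analysis chain.

    Returns a dict of result tables; writes them under ``cfg.out_dir`` when
    set (block_metrics.csv, bivariate_fits.csv, rma_fits.csv,
    climate_rma_fits.csv, sem_paths.csv, sem_summary.json, run_log.json).
    """
    cfg = cfg or RunConfig()
    design = validate_design(data)
    metrics, exclusions = compute_block_metrics(data, cfg)
    bivariate = _bivariate_rows(metrics, cfg)
    rma = _rma_rows(metrics)

    climate_rma = None
    if data.climate is not None:
        site_means = metrics.groupby("site_id")[["log_cv", *DIVERSITY_SCALES]].mean()
        clim = data.climate.set_index("site_id").reindex(site_means.index)
        keep = site_means["log_cv"].notna() & clim.notna().all(axis=1)
        try:
            resid = climate_residualize(site_means.loc[keep, "log_cv"], clim.loc[keep])
            rows = []
            for pred in DIVERSITY_SCALES:
                r = rma_fit(site_means.loc[keep, pred], resid)
                rows.append(
                    {
                        "response": "log_cv_climate_residual",
                        "predictor": pred,
                        "slope": r.slope,
                        "ci_lo": r.ci95[0],
                        "ci_hi": r.ci95[1],
                        "n_sites": r.n,
                    }
                )
            climate_rma = pd.DataFrame(rows)
        except ValueError as exc:
            warnings.warn(f"climate residualization skipped: {exc}")

    with_env = "env_het" in metrics.columns and metrics["env_het"].notna().any()
    dag = observational_dag(with_env_het=with_env)
    sem = fit_sem(dag, metrics, simplify=cfg.simplify_sem)

    results = {
        "design": design,
        "block_metrics": metrics,
        "bivariate": bivariate,
        "rma": rma,
        "climate_rma": climate_rma,
        "sem": sem,
        "run_log": _run_log(cfg, design, exclusions),
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_block_metrics(metrics, out / "block_metrics.csv")
        bivariate.to_csv(out / "bivariate_fits.csv", index=False, float_format="%.17g")
        rma.to_csv(out / "rma_fits.csv", index=False, float_format="%.17g")
        if climate_rma is not None:
            climate_rma.to_csv(out / "climate_rma_fits.csv", index=False, float_format="%.17g")
        sem.path_table.to_csv(out / "sem_paths.csv", index=False, float_format="%.17g")
        (out / "sem_summary.json").write_text(json.dumps(_sem_summary(sem), indent=2))
        (out / "run_log.json").write_text(json.dumps(results["run_log"], indent=2))
    return results


HET_METRICS = ("mu", "sigma", "cv", "covariation", "alpha", "beta_disp", "gamma")


def run_heterogeneity(
    pre: SurveyDataset, post: SurveyDataset, cfg: Optional[RunConfig] = None
) -> dict:
    """The enhanced-heterogeneity analysis on matched pre/post phases."""
    cfg = cfg or RunConfig()
    metrics_pre, excl_pre = compute_block_metrics(pre, cfg)
    metrics_post, excl_post = compute_block_metrics(post, cfg)

    phase_rows = []
    for metric in HET_METRICS:
        try:
            r = treatment_effects(metrics_pre, metrics_post, metric)
            phase_rows.append(
                {
                    "metric": metric,
                    "effect": r.slope,
                    "ci_lo": r.ci95[0],
                    "ci_hi": r.ci95[1],
                    "chi2": r.chi2,
                    "p": r.p,
                    "n_obs": r.n_obs,
                }
            )
        except ValueError as exc:
            phase_rows.append({"metric": metric, "effect": np.nan, "note": str(exc)})
    phase_effects = pd.DataFrame(phase_rows)

    inter_rows = []
    for pred in DIVERSITY_SCALES:
        try:
            r = heterogeneity_interaction(metrics_pre, metrics_post, pred)
            inter_rows.append(
                {
                    "predictor": pred,
                    "interaction_slope": r.slope,
                    "ci_lo": r.ci95[0],
                    "ci_hi": r.ci95[1],
                    "chi2": r.chi2,
                    "p": r.p,
                    "n_obs": r.n_obs,
                }
            )
        except ValueError as exc:
            inter_rows.append({"predictor": pred, "interaction_slope": np.nan, "note": str(exc)})
    interactions = pd.DataFrame(inter_rows)

    dag = observational_dag(with_env_het=False)
    multigroup = multigroup_sem(dag, metrics_pre, metrics_post)

    results = {
        "metrics_pre": metrics_pre,
        "metrics_post": metrics_post,
        "phase_effects": phase_effects,
        "interactions": interactions,
        "multigroup": multigroup,
        "run_log": {
            "seed": cfg.seed,
            "exclusions_pre": excl_pre,
            "exclusions_post": excl_post,
        },
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_block_metrics(metrics_pre, out / "block_metrics_pre.csv")
        write_block_metrics(metrics_post, out / "block_metrics_post.csv")
        phase_effects.to_csv(out / "phase_effects.csv", index=False, float_format="%.17g")
        interactions.to_csv(out / "interactions.csv", index=False, float_format="%.17g")
        multigroup.paths.to_csv(out / "multigroup_paths.csv", index=False, float_format="%.17g")
        (out / "multigroup_summary.json").write_text(
            json.dumps(
                {
                    "fisher_c": {k: list(v) for k, v in multigroup.fisher_c.items()},
                    "n_obs": multigroup.n_obs,
                    "free_paths": multigroup.paths.loc[
                        multigroup.paths["status"] == "free", ["predictor", "response"]
                    ].values.tolist(),
                },
                indent=2,
            )
        )
        (out / "run_log.json").write_text(json.dumps(results["run_log"], indent=2))
    return results
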