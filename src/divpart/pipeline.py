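"""End-to-end analysis: productivity and diversity-effect models + sensitivity.

Orchestrates the full workflow on any :class:`~divpart.core_data.ExperimentTable`
(synthetic or user-supplied):

1. productivity model — square-root total biomass on ln(richness) x
   treatment with the full study-level random structure and AR(1)
   residual correlation (an AIC comparison against compound symmetry is
   reported);
2. diversity-effect models — the standardized net / complementarity /
   selection effects from the additive partition, each modelled with the
   same fixed and random structure; drought runs drop the temporal
   correlation (independent residuals), nutrient runs keep AR(1);
3. sensitivity analyses — excluding monocultures or high-diversity
   communities (richness > 20), recoding treatment by fertilizer type
   (three levels), and adding a nutrient-amount or drought-duration-class
   covariate with its richness and treatment interactions.

Every section of the report records its row counts and filter trail, and
the whole report is deterministic given the input table and config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import core_data, mixed_model, partition, synthetic
from .core_data import CONTROL, ExperimentTable, total_biomass_view
from .mixed_model import ModelSpec, build_design, reml_fit, wald_sequential, \
    compare_covariance, fitted_lines

HIGH_DIVERSITY_THRESHOLD = 20
ALPHA = 0.05


class PipelineError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    alteration_type: str = "nutrient"
    responses: tuple = ("productivity", "net_std", "ce_std", "se_std")
    exclude_monocultures: bool = False
    exclude_high_diversity: bool = False
    high_diversity_threshold: int = HIGH_DIVERSITY_THRESHOLD
    fertilizer_three_level: bool = False
    covariate: str = "none"            # none | n_added | drought_class
    partition_threshold: float = partition.DEFAULT_THRESHOLD
    denominator_scope: str = "study_treatment_year"
    compare_structures: bool = True
    richness_grid: tuple = (1, 2, 4, 8, 16, 32, 60)
    seed: int = 0

    def __post_init__(self):
        if self.alteration_type == "drought" and self.fertilizer_three_level:
            raise PipelineError("drought runs cannot use fertilizer "
                                "three-level coding")
        if self.covariate not in ("none", "n_added", "drought_class"):
            raise PipelineError(f"unknown covariate {self.covariate!r}")


@dataclass
class AnalysisReport:
    """Structured, JSON-serializable analysis output."""

    provenance: dict = field(default_factory=dict)
    sections: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"provenance": self.provenance, "sections": self.sections}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=_jsonify,
                          **kwargs)


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha1(
        pd.util.hash_pandas_object(df, index=False).values.tobytes()
    ).hexdigest()[:12]


def _config_hash(config: AnalysisConfig) -> str:
    return hashlib.sha1(json.dumps(asdict(config), sort_keys=True,
                                   default=str).encode()).hexdigest()[:12]


def _check_inputs(view: pd.DataFrame):
    if view["study_id"].nunique() < 2:
        raise PipelineError("single-study input: study-level random effects "
                            "and treatment tests are not estimable")
    labels = set(view["treatment"].unique())
    if labels == {CONTROL}:
        raise PipelineError("no treated plots: treatment level beyond "
                            f"'{CONTROL}' is missing")
    if CONTROL not in labels:
        raise PipelineError(f"no '{CONTROL}' plots in input")


def _fit_section(df: pd.DataFrame, spec: ModelSpec, grid,
                 compare: bool = True) -> dict:
    design = build_design(df, spec)
    fit = reml_fit(design)
    wald = wald_sequential(fit)
    section = {
        "response": spec.response,
        "residual_correlation": spec.residual_correlation,
        "n_obs": fit.n_obs, "n_plots": fit.n_plots, "n_studies": fit.n_studies,
        "converged": fit.converged,
        "wald": wald.to_dict(orient="records"),
        "fixed_effects": fit.fixed_table().to_dict(orient="records"),
        "variance_components": fit.vc.to_dict(orient="records"),
        "rho": fit.rho_hat, "rho_se": fit.rho_se,
        "sigma2_e": fit.sigma2_e,
        "reml_loglik": fit.reml_loglik, "aic": fit.aic,
        "df_method": "satterthwaite/containment (not Kenward-Roger)",
        "significant_at_alpha": {
            r["term"]: bool(r["p"] < ALPHA) if np.isfinite(r["p"]) else None
            for r in wald.to_dict(orient="records")},
    }
    grid_in_range = [g for g in grid
                     if g <= df["sown_richness"].max() and g >= 1]
    section["fitted_lines_pooled"] = fitted_lines(
        fit, grid_in_range, level="pooled").to_dict(orient="records")
    section["fitted_lines_per_study"] = fitted_lines(
        fit, grid_in_range, level="per_study").to_dict(orient="records")
    if compare and spec.residual_correlation == "ar1":
        spec_cs = ModelSpec(response=spec.response,
                            fixed_terms=spec.fixed_terms,
                            random_terms=spec.random_terms,
                            residual_correlation="compound_symmetry",
                            treatment_coding=spec.treatment_coding)
        fit_cs = reml_fit(build_design(df, spec_cs))
        section["covariance_comparison"] = compare_covariance(fit, fit_cs)
    return section


def _productivity_frame(table: ExperimentTable,
                        config: AnalysisConfig) -> pd.DataFrame:
    view = total_biomass_view(table)
    cov = table.covariates[["study_id", "plot_id", "n_added",
                            "drought_duration_days", "drought_class"]]
    return view.merge(cov, on=["study_id", "plot_id"], how="left")


def run_main(table: ExperimentTable, config: AnalysisConfig) -> AnalysisReport:
    """Productivity model (sqrt response, AR(1)) with AIC structure check."""
    report = AnalysisReport(provenance={
        "config_hash": _config_hash(config), "seed": config.seed,
        "input_digest": _digest(table.records),
        "alteration_type": config.alteration_type,
    })
    validation = core_data.validate_table(table)
    if not validation.ok:
        raise PipelineError(f"table fails validation with "
                            f"{validation.n_errors} error(s); first: "
                            f"{validation.issues[0]}")
    df = _productivity_frame(table, config)
    _check_inputs(df)
    spec = ModelSpec(response="sqrt_total_biomass", residual_correlation="ar1")
    report.sections["productivity"] = _fit_section(
        df, spec, config.richness_grid, compare=config.compare_structures)
    return report


def run_partition_models(table: ExperimentTable, config: AnalysisConfig,
                         report: AnalysisReport | None = None
                         ) -> AnalysisReport:
    """Models for standardized net/CE/SE effects (drought: independent
    residuals, mirroring the simplified structure used when AR(1) fails
    to converge on diversity-effect responses)."""
    if report is None:
        report = AnalysisReport(provenance={
            "config_hash": _config_hash(config), "seed": config.seed,
            "input_digest": _digest(table.records)})
    results = partition.partition_table(
        table, threshold=config.partition_threshold,
        denominator_scope=config.denominator_scope)
    ok = results[results["status"] == "ok"]
    if ok.empty:
        raise PipelineError("all plots degenerate: no partition results "
                            "to model")
    corr = "independent" if config.alteration_type == "drought" else "ar1"
    random_terms = mixed_model.DEFAULT_RANDOM   # plot term kept in both
    report.sections["partition_summary"] = {
        "status_counts": results.attrs.get("status_counts", {}),
        "n_ok": int(len(ok)),
    }
    for response in ("net_std", "ce_std", "se_std"):
        if response not in config.responses:
            continue
        spec = ModelSpec(response=response, residual_correlation=corr,
                         random_terms=random_terms)
        report.sections[response] = _fit_section(
            ok, spec, config.richness_grid,
            compare=config.compare_structures and corr == "ar1")
    return report


def run_sensitivity(table: ExperimentTable, config: AnalysisConfig,
                    report: AnalysisReport | None = None) -> AnalysisReport:
    """Sensitivity refits of the productivity model.

    Each toggle filters or recodes the data, refits, and accounts for the
    removed rows (rows_in = rows_out + rows_removed).
    """
    if report is None:
        report = AnalysisReport(provenance={
            "config_hash": _config_hash(config), "seed": config.seed,
            "input_digest": _digest(table.records)})
    df = _productivity_frame(table, config)
    runs = {}

    def sens_fit(name, sub, spec):
        if sub["sown_richness"].nunique() < 2:
            raise PipelineError(f"sensitivity run {name!r} leaves fewer than "
                                "2 richness levels")
        _check_inputs(sub)
        sec = _fit_section(sub, spec, config.richness_grid, compare=False)
        sec["rows_in"] = int(len(df))
        sec["rows_out"] = int(len(sub))
        sec["rows_removed"] = int(len(df) - len(sub))
        runs[name] = sec

    base_spec = ModelSpec(response="sqrt_total_biomass",
                          residual_correlation="ar1")
    if config.exclude_monocultures:
        sens_fit("exclude_monocultures",
                 df[df["sown_richness"] > 1], base_spec)
    if config.exclude_high_diversity:
        sens_fit("exclude_high_diversity",
                 df[df["sown_richness"] <= config.high_diversity_threshold],
                 base_spec)
    if config.fertilizer_three_level:
        spec3 = ModelSpec(response="sqrt_total_biomass",
                          residual_correlation="ar1",
                          treatment_coding="three_level")
        sens_fit("fertilizer_three_level", df, spec3)
    if config.covariate != "none":
        expected = "n_added" if config.alteration_type == "nutrient" \
            else "drought_class"
        if config.covariate != expected:
            raise PipelineError(
                f"covariate {config.covariate!r} does not apply to "
                f"{config.alteration_type} studies (use {expected!r})")
        spec_cov = ModelSpec(response="sqrt_total_biomass",
                             residual_correlation="ar1",
                             covariate=config.covariate)
        sens_fit(f"covariate_{config.covariate}", df, spec_cov)
    report.sections["sensitivity"] = runs
    return report


def run_all(table: ExperimentTable, config: AnalysisConfig) -> AnalysisReport:
    """Main model, partition models (if species-level data), sensitivity."""
    report = run_main(table, config)
    if table.species_level and any(
            r in config.responses for r in ("net_std", "ce_std", "se_std")):
        run_partition_models(table, config, report)
    if (config.exclude_monocultures or config.exclude_high_diversity
            or config.fertilizer_three_level or config.covariate != "none"):
        run_sensitivity(table, config, report)
    return report


def recovery_study(sim_config: synthetic.SimulationConfig, n_reps: int,
                   seed: int, alpha: float = ALPHA) -> pd.DataFrame:
    """Monte-Carlo parameter recovery for the productivity model.

    Generates ``n_reps`` experiments, fits the productivity model to each,
    and summarizes, per fixed effect: mean estimate, bias, Monte-Carlo
    standard error of the bias, RMSE, 95% CI coverage of the truth, and
    the rejection rate of the sequential Wald test at ``alpha``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    truth = {
        "intercept": sim_config.beta.intercept,
        "ln_richness": sim_config.beta.richness_slope,
        "treatment": sim_config.beta.treatment_effect,
        "ln_richness:treatment": sim_config.beta.interaction,
    }
    spec = ModelSpec(response="sqrt_total_biomass",
                     residual_correlation="ar1")
    est, cover, reject, rhos = [], [], [], []
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                 for s in ss.spawn(n_reps)]
    for rep_seed in rep_seeds:
        cfg = replace(sim_config, seed=rep_seed)
        table, _ = synthetic.generate_experiment(cfg)
        df = _productivity_frame(table, AnalysisConfig(
            alteration_type=cfg.alteration_type))
        fit = reml_fit(build_design(df, spec))
        wald = wald_sequential(fit).set_index("term")
        tab = fit.fixed_table().set_index("term")
        est.append(tab["estimate"])
        cover.append({t: tab.loc[t, "ci_low"] <= truth[t] <= tab.loc[t, "ci_high"]
                      for t in truth})
        reject.append({t: bool(wald.loc[t, "p"] < alpha) for t in truth})
        rhos.append(fit.rho_hat)
    est = pd.DataFrame(est)
    cover = pd.DataFrame(cover)
    reject = pd.DataFrame(reject)
    rows = []
    for t, tv in truth.items():
        e = est[t].to_numpy()
        rows.append({
            "term": t, "truth": tv, "mean_estimate": e.mean(),
            "bias": e.mean() - tv,
            "mc_se": e.std(ddof=1) / np.sqrt(len(e)),
            "rmse": float(np.sqrt(np.mean((e - tv) ** 2))),
            "coverage": float(cover[t].mean()),
            "rejection_rate": float(reject[t].mean()),
        })
    out = pd.DataFrame(rows)
    out.attrs["rho_mean"] = float(np.mean(rhos))
    out.attrs["rho_truth"] = sim_config.rho
    out.attrs["n_reps"] = n_reps
    return out
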