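"""Synthetic multi-site diversity x resource-alteration experiments.

Generates grassland-experiment tables with fully known ground truth so the
partitioning and mixed-model stages can be tested end to end: a sown
richness gradient crossed with a binary resource alteration (nutrient
addition or drought), repeated over years, with study-level random
effects, a plot effect, and AR(1) year-to-year residual correlation.

Construction, on the square-root biomass scale (the analysis scale):

    sqrt(total) = b0 + b1*ln(N) + b2*T + b3*ln(N)*T
                  + study effects + plot effect + AR(1) errors

and the total is squared back. Monoculture plots replace the fixed part by
sqrt(M_i), the species' own monoculture mean (log-normal across species,
multiplied up by nutrient addition and down by drought). Mixture totals
are split among sown species in proportion to

    w_i = max(0, RY_E,i + dRY_i) * M_i

where the injected relative-yield deviations dRY_i carry the
diversity-effect structure (mean deviation increasing with ln N, optional
treatment shift, a selection coupling with monoculture mass, and
species-level scatter). The generator records, per mixture plot, the
noise-free standardized net / complementarity / selection effects
implied by its own draws, evaluated by direct arithmetic independent of
the partition module.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .core_data import CONTROL, ExperimentTable, drought_class


class ConfigurationError(ValueError):
    """Simulation config violates an invariant (e.g. pool < max richness)."""


@dataclass
class FixedEffectTruth:
    """True fixed effects on the square-root-biomass scale (g^0.5 m^-1)."""

    intercept: float = 14.12
    richness_slope: float = 3.01
    treatment_effect: float = 3.39
    interaction: float = -0.34

    def __post_init__(self):
        if self.intercept <= 0:
            raise ConfigurationError("intercept must be > 0")


@dataclass
class VarianceComponentTruth:
    """True random-effect variances (square-root scale, squared units)."""

    study: float = 14.69
    study_richness: float = 2.11
    study_treatment: float = 1.97
    study_richness_treatment: float = 2e-6
    study_time: float = 4.20
    plot: float = 13.86

    def __post_init__(self):
        if any(v < 0 for v in asdict(self).values()):
            raise ConfigurationError("variance components must be >= 0")


@dataclass
class DiversityEffectTruth:
    """Structure of the injected relative-yield deviations dRY.

    Per species i in a mixture of richness N under treatment T:

        dRY_i = (mean_dry_slope + treatment_dry_shift*T
                 + (selection_strength + treatment_selection_shift*T)*z_i
                 + species_sd*u_i) * ln(N)/N

    with z_i the species' standardized log monoculture-mass deviation
    (coupling dRY to M produces selection effects) and u_i independent
    species scatter. RY_E,i + dRY_i is truncated at 0.
    treatment_selection_shift tilts mixture dominance toward
    high-monoculture-mass species under treatment (responsive species
    dominating fertilized mixtures), moving the complementarity/selection
    split without changing plot totals.
    """

    mean_dry_slope: float = 0.2
    treatment_dry_shift: float = 0.0
    selection_strength: float = 0.1
    species_sd: float = 0.1
    treatment_selection_shift: float = 0.0


@dataclass
class SimulationConfig:
    n_studies: int = 6
    richness_levels: tuple = (1, 2, 4, 8, 16)
    plots_per_richness_per_treatment: int = 2
    mono_plots_per_species: int = 1
    n_years: int = 3
    pool_size: int = 16
    alteration_type: str = "nutrient"          # or "drought"
    beta: FixedEffectTruth = field(default_factory=FixedEffectTruth)
    vc: VarianceComponentTruth = field(default_factory=VarianceComponentTruth)
    rho: float = 0.10                          # AR(1) coefficient
    resid_sd: float = 3.0                      # marginal sd of AR(1) errors
    noise_sd: float = 0.0                      # extra iid noise, sqrt scale
    lognormal_noise_sd: float = 0.0            # misspecification toggle
    delta_ry: DiversityEffectTruth = field(default_factory=DiversityEffectTruth)
    mono_sigma: float = 0.4                    # log-normal scatter of M across species
    species_level: bool = True                 # per-species biomass vs totals only
    mono_threshold: float = 2.5                # exclusion threshold used for truth
    covariate_effect: float = 0.0              # sqrt-scale per-unit covariate x T
    seed: int = 0

    def __post_init__(self):
        levels = tuple(int(n) for n in self.richness_levels)
        if levels != tuple(sorted(levels)) or any(n < 1 for n in levels):
            raise ConfigurationError("richness levels must be sorted positive ints")
        if 1 not in levels:
            raise ConfigurationError("monoculture level 1 required "
                                     "(partition denominators)")
        self.richness_levels = levels
        for name in ("n_studies", "plots_per_richness_per_treatment",
                     "mono_plots_per_species", "n_years", "pool_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.pool_size < max(levels):
            raise ConfigurationError(
                f"pool_size {self.pool_size} < max richness {max(levels)}")
        if not -1 < self.rho < 1:
            raise ConfigurationError("rho must be in (-1, 1)")
        if self.resid_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("noise sds must be >= 0")
        if self.alteration_type not in ("nutrient", "drought"):
            raise ConfigurationError(f"unknown alteration {self.alteration_type!r}")


def drought_config(**overrides) -> SimulationConfig:
    """Drought study conditions: fewer studies with species-level biomass,
    a negative treatment effect, and near-zero residual autocorrelation."""
    base = dict(
        n_studies=3,
        alteration_type="drought",
        beta=FixedEffectTruth(intercept=9.52, richness_slope=2.03,
                              treatment_effect=-1.18, interaction=-0.29),
        vc=VarianceComponentTruth(study=9.66, study_richness=0.94,
                                  study_treatment=0.08,
                                  study_richness_treatment=2e-6,
                                  study_time=2.92, plot=11.50),
        rho=0.05,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def nutrient_headline_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Nutrient-addition study conditions for the headline diversity-effect
    contrast: six studies with species-level biomass at realistic plot
    counts (~120 plots per study), no productivity-scale
    richness x treatment interaction, and mixture dominance tilted toward
    high-monoculture-mass (nutrient-responsive) species under enrichment."""
    base = dict(
        n_studies=6,
        mono_plots_per_species=4,
        plots_per_richness_per_treatment=10,
        beta=FixedEffectTruth(intercept=14.12, richness_slope=3.01,
                              treatment_effect=3.39, interaction=0.0),
        delta_ry=DiversityEffectTruth(
            mean_dry_slope=0.2, treatment_dry_shift=-0.1,
            selection_strength=0.1, species_sd=0.1,
            treatment_selection_shift=0.3),
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def drought_headline_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Drought counterpart: three species-level studies, no interaction on
    any channel (totals, mean deviations, or dominance tilt)."""
    base = dict(
        mono_plots_per_species=4,
        plots_per_richness_per_treatment=10,
        beta=FixedEffectTruth(intercept=9.52, richness_slope=2.03,
                              treatment_effect=-1.18, interaction=0.0),
        seed=seed,
    )
    base.update(overrides)
    return drought_config(**base)


@dataclass
class TrueParameters:
    """Ground truth attached to a generated table.

    ``true_effects`` has one row per mixture plot with the noise-free
    standardized net / complementarity / selection effects; a partition of
    the noise-free table must reproduce them exactly.
    """

    beta: FixedEffectTruth
    vc: VarianceComponentTruth
    rho: float
    resid_sd: float
    delta_ry: DiversityEffectTruth
    true_effects: pd.DataFrame = None
    truncation_rate: float = 0.0
    clamp_rate: float = 0.0


def _stream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Named independent substream of the master seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key, index)))


def _treated_label(config: SimulationConfig, study_index: int) -> str:
    if config.alteration_type == "drought":
        return "drought"
    return "NPK" if study_index % 2 == 0 else "NH4NO3"


def generate_species_pool(config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-study species pools with monoculture means by treatment.

    Columns: study_id, species_id, z (standardized log deviation of the
    monoculture mean), u (independent dRY propensity), M_control,
    M_treated. E[sqrt(M)] equals intercept (+ treatment_effect when
    treated), so the treatment acts multiplicatively on M: factor > 1 for
    nutrient addition, < 1 for drought.
    """
    rows = []
    for s in range(config.n_studies):
        srng = rng if rng is not None else _stream(config.seed, "pool", s)
        z = srng.standard_normal(config.pool_size)
        u = srng.standard_normal(config.pool_size)
        sig = config.mono_sigma
        scatter = np.exp(sig * z - sig**2 / 4.0)   # E[sqrt(scatter)] = 1
        b = config.beta
        for i in range(config.pool_size):
            rows.append({
                "study_id": f"study{s:02d}",
                "species_id": f"sp{i:02d}",
                "z": z[i],
                "u": u[i],
                "M_control": b.intercept**2 * scatter[i],
                "M_treated": (b.intercept + b.treatment_effect)**2 * scatter[i],
            })
    return pd.DataFrame(rows)


def compose_mixture_biomass(mono_means, proportions, dry) -> np.ndarray:
    """Per-species mixture biomass Y_i = max(0, RY_E,i + dRY_i) * M_i."""
    mono_means = np.asarray(mono_means, dtype=float)
    proportions = np.asarray(proportions, dtype=float)
    dry = np.asarray(dry, dtype=float)
    if not np.isclose(proportions.sum(), 1.0):
        raise ConfigurationError("sown proportions must sum to 1")
    if np.any(mono_means <= 0):
        raise ConfigurationError("monoculture means must be > 0")
    return np.maximum(0.0, proportions + dry) * mono_means


def true_partition(mono_means, proportions, dry, denominator=None,
                   total=None, threshold: float = 2.5) -> dict:
    """Closed-form standardized net/CE/SE for one mixture plot.

    Evaluates the additive partition directly on the generator's own
    quantities (independent arithmetic, no call into the partition
    module). ``total`` defaults to sum(max(0, RY_E+dRY)*M), i.e. the
    un-rescaled composition; the generator passes its noise-free plot
    total instead. ``denominator`` defaults to mean(M) over species above
    the exclusion threshold.
    """
    m = np.asarray(mono_means, dtype=float)
    p = np.asarray(proportions, dtype=float)
    d = np.asarray(dry, dtype=float)
    w = np.maximum(0.0, p + d) * m
    if total is None:
        total = w.sum()
    usable = m >= threshold
    n = int(usable.sum())
    if n < 2:
        return {"status": "degenerate", "net_std": np.nan,
                "ce_std": np.nan, "se_std": np.nan}
    if w.sum() <= 0:
        y_obs = np.full(len(m), total / len(m))
    else:
        y_obs = total * w / w.sum()
    m_u, y_u = m[usable], y_obs[usable]
    p_u = p[usable] / p[usable].sum()
    d_obs = y_u / m_u - p_u
    net = y_u.sum() - (p_u * m_u).sum()
    ce = n * d_obs.mean() * m_u.mean()
    se = n * (np.mean(d_obs * m_u) - d_obs.mean() * m_u.mean())
    if denominator is None:
        denominator = m_u.mean()
    return {"status": "ok", "net_std": net / denominator,
            "ce_std": ce / denominator, "se_std": se / denominator,
            "net_raw": net, "ce_raw": ce, "se_raw": se,
            "denominator": denominator}


def _ar1_errors(rng, n_years, rho, sd) -> np.ndarray:
    """Stationary AR(1) path with marginal standard deviation ``sd``."""
    e = np.empty(n_years)
    e[0] = rng.standard_normal() * sd
    innov_sd = sd * np.sqrt(max(0.0, 1.0 - rho**2))
    for t in range(1, n_years):
        e[t] = rho * e[t - 1] + innov_sd * rng.standard_normal()
    return e


def generate_experiment(config: SimulationConfig
                        ) -> tuple[ExperimentTable, TrueParameters]:
    """Generate one multi-study experiment table plus its ground truth.

    Deterministic under a fixed config (one master seed, independent named
    substreams per study). With every variance, noise sd, mono_sigma and
    dRY truth at zero, plot totals equal the squared fixed part exactly.
    """
    b, vc, dr = config.beta, config.vc, config.delta_ry
    years = np.arange(1, config.n_years + 1)
    rec_rows, cov_rows, truth_rows = [], [], []
    n_trunc = n_w = n_clamp = n_eta = 0

    for s in range(config.n_studies):
        study = f"study{s:02d}"
        pool = generate_species_pool(
            replace(config, n_studies=1, seed=config.seed),
            rng=_stream(config.seed, "pool", s))
        pool = pool.assign(study_id=study)
        re_rng = _stream(config.seed, "study_effects", s)
        plot_rng = _stream(config.seed, "plots", s)
        err_rng = _stream(config.seed, "errors", s)
        b0 = re_rng.standard_normal() * np.sqrt(vc.study)
        b1 = re_rng.standard_normal() * np.sqrt(vc.study_richness)
        b2 = re_rng.standard_normal() * np.sqrt(vc.study_treatment)
        b3 = re_rng.standard_normal() * np.sqrt(vc.study_richness_treatment)
        bt = re_rng.standard_normal(config.n_years) * np.sqrt(vc.study_time)

        treated_label = _treated_label(config, s)
        if config.alteration_type == "nutrient":
            n_added = float(5 * (1 + s % 4))            # 5..20 g N m-2 yr-1
            duration = 0.0
        else:
            n_added = 0.0
            duration = 140.0 + 10 * s if s % 3 == 2 else 30.0 + 5 * s
        cov_value = n_added if config.alteration_type == "nutrient" else \
            float(duration >= 60)

        # ---- plot roster -------------------------------------------------
        plots = []   # (plot_id, richness, T, members: DataFrame | None)
        pid = 0
        for trt in (0, 1):
            if config.species_level:
                for _, sp in pool.iterrows():
                    for _ in range(config.mono_plots_per_species):
                        plots.append((f"p{pid:03d}", 1, trt,
                                      pool[pool.species_id == sp.species_id]))
                        pid += 1
            else:
                for _ in range(config.plots_per_richness_per_treatment):
                    plots.append((f"p{pid:03d}", 1, trt, None))
                    pid += 1
            for n_sp in config.richness_levels:
                if n_sp == 1:
                    continue
                for _ in range(config.plots_per_richness_per_treatment):
                    members = pool.iloc[plot_rng.choice(
                        config.pool_size, size=n_sp, replace=False)]
                    plots.append((f"p{pid:03d}", n_sp, trt,
                                  members if config.species_level else None))
                    pid += 1

        # ---- biomass per plot-year --------------------------------------
        for plot_id, n_sp, trt, members in plots:
            lnN = np.log(n_sp)
            treatment = treated_label if trt else CONTROL
            mcol = "M_treated" if trt else "M_control"
            if n_sp == 1 and config.species_level:
                sp = members.iloc[0]
                eta_fix = np.sqrt(sp[mcol])
            else:
                eta_fix = (b.intercept + b.richness_slope * lnN
                           + b.treatment_effect * trt + b.interaction * lnN * trt)
            eta_fix = eta_fix + config.covariate_effect * trt * cov_value
            eta_rand = (b0 + b1 * lnN + b2 * trt + b3 * lnN * trt
                        + plot_rng.standard_normal() * np.sqrt(vc.plot))
            errs = _ar1_errors(err_rng, config.n_years, config.rho, config.resid_sd)
            if config.noise_sd > 0:
                errs = errs + err_rng.standard_normal(config.n_years) * config.noise_sd

            if n_sp >= 2 and config.species_level:
                slope = dr.mean_dry_slope + dr.treatment_dry_shift * trt
                coupling = (dr.selection_strength
                            + dr.treatment_selection_shift * trt)
                e_sp = (coupling * members["z"].to_numpy()
                        + dr.species_sd * members["u"].to_numpy())
                dry = (slope + e_sp) * lnN / n_sp
                props = np.full(n_sp, 1.0 / n_sp)
                w = np.maximum(0.0, props + dry) * members[mcol].to_numpy()
                n_trunc += int((props + dry < 0).sum())
                n_w += n_sp
                shares = (w / w.sum()) if w.sum() > 0 else props
                tp = true_partition(members[mcol].to_numpy(), props, dry,
                                    denominator=None, total=max(0.0, eta_fix)**2,
                                    threshold=config.mono_threshold)
                # denominator under the scope "study x treatment x year":
                # noise-free mono means are the pool's M values
                pool_m = pool[mcol].to_numpy()
                denom = pool_m[pool_m >= config.mono_threshold].mean()
                truth_rows.append({
                    "study_id": study, "plot_id": plot_id,
                    "sown_richness": n_sp, "treatment": treatment,
                    "net_std": tp["net_raw"] / denom,
                    "ce_std": tp["ce_raw"] / denom,
                    "se_std": tp["se_raw"] / denom,
                })
            else:
                shares = None

            for iy, year in enumerate(years):
                eta = eta_fix + eta_rand + bt[iy] + errs[iy]
                if eta < 0:
                    n_clamp += 1
                n_eta += 1
                total = max(0.0, eta)**2
                if config.lognormal_noise_sd > 0:
                    sln = config.lognormal_noise_sd
                    total *= err_rng.lognormal(-sln**2 / 2.0, sln)
                if shares is None:
                    sp_ids = ([members.iloc[0].species_id]
                              if (members is not None) else ["TOTAL"])
                    rec_rows.append((study, plot_id, int(year), n_sp, treatment,
                                     sp_ids[0], 1.0, total))
                else:
                    for sp_id, share in zip(members["species_id"], shares):
                        rec_rows.append((study, plot_id, int(year), n_sp,
                                         treatment, sp_id, 1.0 / n_sp,
                                         total * share))
            # dose covariates are study-level design attributes (the rate
            # applied to that study's treated plots), recorded on every plot
            cov_rows.append({
                "study_id": study, "plot_id": plot_id,
                "alteration_type": config.alteration_type,
                "n_added": n_added,
                "drought_duration_days": duration,
            })

    records = pd.DataFrame(rec_rows, columns=[
        "study_id", "plot_id", "year", "sown_richness", "treatment",
        "species_id", "sown_proportion", "biomass"])
    covariates = pd.DataFrame(cov_rows)
    covariates["drought_class"] = covariates["drought_duration_days"].map(
        drought_class)
    table = ExperimentTable(records=records, covariates=covariates,
                            provenance=f"divpart-synthetic seed={config.seed}")
    truth = TrueParameters(
        beta=b, vc=vc, rho=config.rho, resid_sd=config.resid_sd, delta_ry=dr,
        true_effects=pd.DataFrame(
            truth_rows, columns=["study_id", "plot_id", "sown_richness",
                                 "treatment", "net_std", "ce_std", "se_std"]),
        truncation_rate=(n_trunc / n_w) if n_w else 0.0,
        clamp_rate=(n_clamp / n_eta) if n_eta else 0.0,
    )
    return table, truth


def noise_free(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with every stochastic component switched off."""
    return replace(config,
                   vc=VarianceComponentTruth(0, 0, 0, 0, 0, 0),
                   resid_sd=0.0, noise_sd=0.0, lognormal_noise_sd=0.0)
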