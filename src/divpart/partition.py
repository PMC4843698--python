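"""Additive partition of biodiversity effects (net = complementarity + selection).

For a mixture plot-year with species observed biomasses Y_O,i and mean
monoculture biomasses M_i (averaged over that species' monoculture plots
within the same study, treatment and year):

    RY_O,i = Y_O,i / M_i          observed relative yield
    RY_E,i = sown proportion      expected relative yield (1/N substitutive)
    dRY_i  = RY_O,i - RY_E,i

    net = sum_i Y_O,i - sum_i RY_E,i * M_i
    CE  = N * mean(dRY) * mean(M)
    SE  = N * cov(dRY, M)         population covariance (divide by N)

so the identity net = CE + SE is exact. Species whose mean monoculture
biomass falls below a threshold (default 2.5 g m-2; relative yields blow
up as M -> 0) are excluded, as are species without monoculture data in
their treatment-year; expected proportions are renormalized over the
surviving species and the drops are listed per plot. Effects are
standardized to dimensionless form by dividing by the mean monoculture
biomass of the corresponding treatment (default grouping: study x
treatment x year, configurable) so they are comparable across treatments
of very different productivity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import ExperimentTable, TOTAL_SPECIES

DEFAULT_THRESHOLD = 2.5   # g m-2, monoculture-mean exclusion threshold

DENOMINATOR_SCOPES = {
    "study_treatment_year": ["study_id", "treatment", "year"],
    "study_treatment": ["study_id", "treatment"],
    "treatment": ["treatment"],
}

RESULT_COLUMNS = [
    "study_id", "plot_id", "year", "treatment", "sown_richness", "n_used",
    "net_raw", "ce_raw", "se_raw", "net_std", "ce_std", "se_std",
    "denominator", "excluded_species", "missing_species", "status",
]


class PartitionInputError(ValueError):
    """Table cannot support partitioning (no species-level biomass)."""


def mean_monoculture_biomass(table: ExperimentTable,
                             threshold: float = DEFAULT_THRESHOLD
                             ) -> pd.DataFrame:
    """Mean monoculture biomass per (study, treatment, year, species).

    Averages over that species' monoculture plots; ``excluded`` is set
    when the mean falls below ``threshold``. Raises
    :class:`PartitionInputError` when the table records only plot totals.
    """
    if not table.species_level:
        raise PartitionInputError(
            "partition requires species-level biomass; this table records "
            "plot totals only")
    rec = table.records
    mono = rec[rec["sown_richness"] == 1]
    if mono.empty:
        raise PartitionInputError("no monoculture plots in table")
    out = (mono.groupby(["study_id", "treatment", "year", "species_id"],
                        as_index=False)
           .agg(mean_mono_biomass=("biomass", "mean"),
                n_mono_plots=("biomass", "size")))
    out["excluded"] = out["mean_mono_biomass"] < threshold
    return out


def partition_plot(plot_records: pd.DataFrame, monos: pd.DataFrame) -> dict:
    """Partition a single mixture plot-year.

    ``plot_records``: species rows of one (study, plot, year);
    ``monos``: output of :func:`mean_monoculture_biomass`. Returns a dict
    with raw effects (standardization is a separate step) and a status in
    {ok, no_monoculture_data, degenerate}.
    """
    first = plot_records.iloc[0]
    if first["sown_richness"] < 2:
        raise ValueError("partition is defined for mixtures (richness >= 2)")
    base = {
        "study_id": first["study_id"], "plot_id": first["plot_id"],
        "year": int(first["year"]), "treatment": first["treatment"],
        "sown_richness": int(first["sown_richness"]),
        "net_raw": np.nan, "ce_raw": np.nan, "se_raw": np.nan,
        "net_std": np.nan, "ce_std": np.nan, "se_std": np.nan,
        "denominator": np.nan,
    }
    m = monos[(monos["study_id"] == first["study_id"])
              & (monos["treatment"] == first["treatment"])
              & (monos["year"] == first["year"])]
    merged = plot_records.merge(
        m[["species_id", "mean_mono_biomass", "excluded"]],
        on="species_id", how="left")
    missing = merged[merged["mean_mono_biomass"].isna()]["species_id"].tolist()
    excluded = merged[merged["excluded"] == True]["species_id"].tolist()  # noqa: E712
    usable = merged[(~merged["mean_mono_biomass"].isna())
                    & (merged["excluded"] != True)]  # noqa: E712
    n = len(usable)
    base["excluded_species"] = ";".join(excluded)
    base["missing_species"] = ";".join(missing)
    base["n_used"] = n
    if n < 2:
        base["status"] = "no_monoculture_data" if missing else "degenerate"
        return base

    M = usable["mean_mono_biomass"].to_numpy(float)
    if np.any(M <= 0):
        raise ArithmeticError(
            "non-positive monoculture mean among usable species "
            "(exclusion threshold must be > 0)")
    y_obs = usable["biomass"].to_numpy(float)
    props = usable["sown_proportion"].to_numpy(float)
    ry_e = props / props.sum()          # renormalized over usable species
    dry = y_obs / M - ry_e
    net = y_obs.sum() - float(ry_e @ M)
    ce = n * dry.mean() * M.mean()
    se = n * float(np.mean(dry * M) - dry.mean() * M.mean())
    base.update(net_raw=net, ce_raw=ce, se_raw=se, status="ok")
    return base


def standardize(results: pd.DataFrame, monos: pd.DataFrame,
                scope: str = "study_treatment_year") -> pd.DataFrame:
    """Divide raw effects by the mean monoculture biomass of the treatment.

    The denominator is the mean of the non-excluded monoculture means
    within the scope group (default study x treatment x year; narrower
    pooling never mixes studies of different productivity scales). Plots
    whose group has no usable monoculture rows become degenerate.
    """
    if scope not in DENOMINATOR_SCOPES:
        raise ValueError(f"unknown denominator scope {scope!r}; "
                         f"choose from {sorted(DENOMINATOR_SCOPES)}")
    keys = DENOMINATOR_SCOPES[scope]
    usable = monos[~monos["excluded"]]
    denom = (usable.groupby(keys, as_index=False)
             .agg(denominator=("mean_mono_biomass", "mean")))
    out = results.drop(columns=["denominator"]).merge(denom, on=keys, how="left")
    ok = out["status"] == "ok"
    good = ok & out["denominator"].notna() & (out["denominator"] > 0)
    out.loc[ok & ~good, "status"] = "degenerate"
    for raw, std in (("net_raw", "net_std"), ("ce_raw", "ce_std"),
                     ("se_raw", "se_std")):
        out.loc[good, std] = out.loc[good, raw] / out.loc[good, "denominator"]
        out.loc[~good, std] = np.nan
    return out[RESULT_COLUMNS]


def partition_table(table: ExperimentTable,
                    threshold: float = DEFAULT_THRESHOLD,
                    denominator_scope: str = "study_treatment_year"
                    ) -> pd.DataFrame:
    """Partition every mixture plot-year of a table; monocultures skipped.

    Returns one row per mixture plot-year with raw and standardized
    effects, the denominator used, dropped species, and a status column;
    a summary of status counts is available via ``.attrs['status_counts']``.
    """
    monos = mean_monoculture_biomass(table, threshold=threshold)
    rec = table.records
    mixtures = rec[(rec["sown_richness"] >= 2)
                   & (rec["species_id"] != TOTAL_SPECIES)]
    rows = []
    for _, grp in mixtures.groupby(["study_id", "plot_id", "year"], sort=True):
        rows.append(partition_plot(grp, monos))
    if not rows:
        out = pd.DataFrame(columns=RESULT_COLUMNS)
        out.attrs["status_counts"] = {}
        return out
    out = standardize(pd.DataFrame(rows), monos, scope=denominator_scope)
    out.attrs["status_counts"] = out["status"].value_counts().to_dict()
    return out
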