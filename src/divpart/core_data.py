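"""Typed data model and validated I/O for multi-site plant-diversity experiments.

The package's lingua franca is the :class:`ExperimentTable`: long-format
plot x year x species above-ground biomass records (g m-2) from grassland
experiments that cross a sown species-richness gradient with a resource
alteration (nutrient addition or drought), plus per-plot design covariates.

Files are plain delimited text (comma by default, tab supported), UTF-8,
with a header row. Canonical columns::

    study_id, plot_id, year, sown_richness, treatment, species_id,
    sown_proportion, biomass, alteration_type, n_added,
    drought_duration_days

Heterogeneous source schemas are accommodated through a *dialect*: a
mapping from canonical names to the file's column names (optionally read
from a YAML file). Tables that only record total plot biomass are read with
``species_id = "TOTAL"`` and ``sown_proportion = 1``; they support the
productivity models but are flagged unusable for partitioning.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: Canonical record (species-level) columns, in write order.
RECORD_COLUMNS = [
    "study_id",
    "plot_id",
    "year",
    "sown_richness",
    "treatment",
    "species_id",
    "sown_proportion",
    "biomass",
]

#: Canonical per-plot covariate columns.
COVARIATE_COLUMNS = [
    "study_id",
    "plot_id",
    "alteration_type",
    "n_added",
    "drought_duration_days",
]

#: Treatment label that marks unmanipulated plots.
CONTROL = "control"

#: Drought shorter than this many days is classed "short", else "long".
DROUGHT_CLASS_CUTOFF_DAYS = 60

#: Sentinel species id for tables that only record total plot biomass.
TOTAL_SPECIES = "TOTAL"


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class TableValidationError(ValueError):
    """A record violates a hard invariant (e.g. negative biomass)."""


class DuplicateKeyError(ValueError):
    """Duplicate (study, plot, year, species) rows."""


def drought_class(duration_days: float) -> str:
    """Classify drought duration: 'short' below 60 days, 'long' otherwise."""
    return "short" if duration_days < DROUGHT_CLASS_CUTOFF_DAYS else "long"


@dataclass
class ExperimentTable:
    """Long-format experiment data: species records + per-plot covariates.

    Attributes
    ----------
    records:
        One row per (study, plot, year, species) with sown design and
        biomass (g m-2). Columns: :data:`RECORD_COLUMNS`.
    covariates:
        One row per (study, plot) with alteration type and treatment
        covariates. Columns: :data:`COVARIATE_COLUMNS`.
    provenance:
        Free text: generator seed, source file, etc.
    """

    records: pd.DataFrame
    covariates: pd.DataFrame
    provenance: str = ""

    @property
    def species_level(self) -> bool:
        """Whether per-species biomass is available (required for partitioning)."""
        return not (self.records["species_id"] == TOTAL_SPECIES).all()

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, ExperimentTable):
            return NotImplemented
        a = self.records.sort_values(RECORD_COLUMNS[:6]).reset_index(drop=True)
        b = other.records.sort_values(RECORD_COLUMNS[:6]).reset_index(drop=True)
        ca = self.covariates.sort_values(["study_id", "plot_id"]).reset_index(drop=True)
        cb = other.covariates.sort_values(["study_id", "plot_id"]).reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a[RECORD_COLUMNS], b[RECORD_COLUMNS],
                                          check_dtype=False)
            pd.testing.assert_frame_equal(ca[COVARIATE_COLUMNS], cb[COVARIATE_COLUMNS],
                                          check_dtype=False)
        except AssertionError:
            return False
        return True


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_table`: counts plus a list of issues.

    ``issues`` entries are ``(severity, message, locator)`` with severity in
    {"error", "warning"}; any "error" should block downstream stages.
    """

    n_studies: int = 0
    n_plots: int = 0
    n_plot_years: int = 0
    issues: list = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return sum(1 for sev, _, _ in self.issues if sev == "error")

    @property
    def ok(self) -> bool:
        return self.n_errors == 0


def load_dialect(path) -> dict:
    """Load a canonical-name -> file-column-name mapping from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise SchemaError(f"dialect file {path!r} must contain a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def _require(df: pd.DataFrame, columns, context: str):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {context}")


def read_experiment_table(path, dialect: dict | None = None,
                          sep: str = ",") -> ExperimentTable:
    """Read a delimited experiment file into a validated :class:`ExperimentTable`.

    Parameters
    ----------
    path:
        Delimited text file (or file-like object) with a header row; record
        and covariate columns may live in one flat file (covariates repeated
        per record row).
    dialect:
        Optional mapping from canonical column names to the file's names.
        A dialect that omits ``species_id``/``sown_proportion`` yields a
        total-biomass-only table (``species_id = "TOTAL"``).
    sep:
        Field delimiter; comma by default, "\\t" supported.

    Raises
    ------
    SchemaError
        A required column is missing (the error names it).
    TableValidationError
        Negative biomass (the error carries a row locator).
    DuplicateKeyError
        Duplicated (study, plot, year, species) rows.
    """
    raw = pd.read_csv(path, sep=sep)
    if dialect:
        rename = {v: k for k, v in dialect.items() if v in raw.columns}
        missing = [k for k, v in dialect.items() if v not in raw.columns]
        if missing:
            raise SchemaError(f"dialect names columns absent from file: {missing}")
        raw = raw.rename(columns=rename)

    base = ["study_id", "plot_id", "year", "sown_richness", "treatment", "biomass"]
    _require(raw, base, "experiment table")

    df = raw.copy()
    if "species_id" not in df.columns:
        df["species_id"] = TOTAL_SPECIES
        df["sown_proportion"] = 1.0
    if "sown_proportion" not in df.columns:
        if (df["species_id"] != TOTAL_SPECIES).any():
            raise SchemaError("missing required column(s) ['sown_proportion'] "
                              "for species-level data")
        df["sown_proportion"] = 1.0

    df["year"] = df["year"].astype(int)
    df["sown_richness"] = df["sown_richness"].astype(int)
    df["biomass"] = df["biomass"].astype(float)
    df["sown_proportion"] = df["sown_proportion"].astype(float)
    for col in ("study_id", "plot_id", "treatment", "species_id"):
        df[col] = df[col].astype(str)

    neg = df.index[df["biomass"] < 0]
    if len(neg):
        i = int(neg[0])
        row = df.loc[i]
        raise TableValidationError(
            f"negative biomass {row['biomass']} at row {i} "
            f"(study={row['study_id']}, plot={row['plot_id']}, "
            f"year={row['year']}, species={row['species_id']})")

    key = ["study_id", "plot_id", "year", "species_id"]
    dup = df.duplicated(key)
    if dup.any():
        first = df.loc[dup.idxmax(), key].tolist()
        raise DuplicateKeyError(f"duplicate (study, plot, year, species) rows, "
                                f"first at {tuple(first)}")

    records = df[RECORD_COLUMNS].reset_index(drop=True)

    if "alteration_type" in df.columns:
        cov = (df[[c for c in COVARIATE_COLUMNS if c in df.columns]]
               .drop_duplicates(["study_id", "plot_id"])
               .reset_index(drop=True))
        for col in ("n_added", "drought_duration_days"):
            if col not in cov.columns:
                cov[col] = 0.0
        cov = cov[COVARIATE_COLUMNS]
    else:
        cov = records[["study_id", "plot_id"]].drop_duplicates().reset_index(drop=True)
        cov["alteration_type"] = "nutrient"
        cov["n_added"] = 0.0
        cov["drought_duration_days"] = 0.0
    cov["n_added"] = cov["n_added"].astype(float)
    cov["drought_duration_days"] = cov["drought_duration_days"].astype(float)
    cov["drought_class"] = cov["drought_duration_days"].map(drought_class)

    return ExperimentTable(records=records, covariates=cov,
                           provenance=str(getattr(path, "name", path)))


def write_experiment_table(table: ExperimentTable, path, sep: str = ",") -> None:
    """Write an :class:`ExperimentTable` to one flat delimited file.

    Covariate columns are repeated on every record row so the file
    round-trips through :func:`read_experiment_table` losslessly.
    """
    cov = table.covariates[COVARIATE_COLUMNS]
    flat = table.records.merge(cov, on=["study_id", "plot_id"], how="left")
    flat.to_csv(path, sep=sep, index=False)


def validate_table(table: ExperimentTable, proportion_tol: float = 1e-9
                   ) -> ValidationReport:
    """Check every table invariant; report problems instead of raising.

    Errors reported: negative biomass; non-finite biomass; sown proportions
    not summing to 1 within a plot-year; monoculture plot-years with more
    than one species record; richness < 1 or year < 1; plots without
    covariate rows; treatment varying within a plot. Year gaps within a
    plot are reported as warnings (the AR(1) residual model handles them
    via power-of-lag correlation but the design intent is consecutive
    years).
    """
    rep = ValidationReport()
    rec = table.records
    rep.n_studies = rec["study_id"].nunique()
    rep.n_plots = len(rec[["study_id", "plot_id"]].drop_duplicates())
    rep.n_plot_years = len(rec[["study_id", "plot_id", "year"]].drop_duplicates())

    def err(msg, loc):
        rep.issues.append(("error", msg, loc))

    def warn(msg, loc):
        rep.issues.append(("warning", msg, loc))

    bad = rec[(rec["biomass"] < 0) | ~np.isfinite(rec["biomass"])]
    for _, r in bad.iterrows():
        err(f"invalid biomass {r['biomass']}",
            (r["study_id"], r["plot_id"], r["year"], r["species_id"]))
    for _, r in rec[rec["sown_richness"] < 1].iterrows():
        err("sown_richness < 1", (r["study_id"], r["plot_id"]))
    for _, r in rec[rec["year"] < 1].iterrows():
        err("year < 1", (r["study_id"], r["plot_id"], r["year"]))

    grp = rec.groupby(["study_id", "plot_id", "year"], sort=False)
    psum = grp["sown_proportion"].sum()
    for loc, s in psum[(psum - 1.0).abs() > proportion_tol].items():
        err(f"sown proportions sum to {s:.6g}, not 1", loc)
    nsp = grp["species_id"].nunique()
    rich = grp["sown_richness"].first()
    for loc in nsp[(rich == 1) & (nsp > 1)].index:
        err("monoculture plot-year has more than one species record", loc)

    cov_keys = set(map(tuple, table.covariates[["study_id", "plot_id"]].values))
    for loc in set(map(tuple, rec[["study_id", "plot_id"]].values)) - cov_keys:
        err("plot has no covariate row", loc)

    ptre = rec.groupby(["study_id", "plot_id"])["treatment"].nunique()
    for loc in ptre[ptre > 1].index:
        err("treatment varies within plot across years", loc)

    years = rec.groupby(["study_id", "plot_id"])["year"].agg(["min", "max", "nunique"])
    gapped = years[(years["max"] - years["min"] + 1) != years["nunique"]]
    for loc in gapped.index:
        warn("year gaps within plot (AR(1) uses power-of-lag correlation)", loc)

    return rep


def total_biomass_view(table: ExperimentTable) -> pd.DataFrame:
    """One row per plot-year with total (summed over species) biomass.

    Returns columns: study_id, plot_id, year, sown_richness, treatment,
    total_biomass. Row count equals the number of distinct
    (study, plot, year) triples.
    """
    grp = table.records.groupby(
        ["study_id", "plot_id", "year"], sort=False, as_index=False)
    out = grp.agg(sown_richness=("sown_richness", "first"),
                  treatment=("treatment", "first"),
                  total_biomass=("biomass", "sum"))
    return out


def table_from_string(text: str, **kwargs) -> ExperimentTable:
    """Convenience: parse an in-memory delimited string (tests, docs)."""
    return read_experiment_table(io.StringIO(text), **kwargs)
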