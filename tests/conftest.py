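"""Shared fixtures: hand-built worked-example plots and small generated tables."""

import numpy as np
import pandas as pd
import pytest

import divpart as dp


def make_plot_records(study, plot, year, treatment, biomasses,
                      species=None, richness=None, proportions=None):
    """Species rows for one mixture plot-year."""
    n = len(biomasses)
    species = species or [f"sp{i}" for i in range(n)]
    richness = richness or n
    proportions = proportions or [1.0 / n] * n
    return pd.DataFrame({
        "study_id": study, "plot_id": plot, "year": year,
        "sown_richness": richness, "treatment": treatment,
        "species_id": species, "sown_proportion": proportions,
        "biomass": [float(b) for b in biomasses],
    })


def make_monos(study, treatment, year, means, species=None, threshold=2.5):
    """Monoculture-mean table for one study/treatment/year."""
    n = len(means)
    species = species or [f"sp{i}" for i in range(n)]
    df = pd.DataFrame({
        "study_id": study, "treatment": treatment, "year": year,
        "species_id": species,
        "mean_mono_biomass": [float(m) for m in means],
        "n_mono_plots": 1,
    })
    df["excluded"] = df["mean_mono_biomass"] < threshold
    return df


@pytest.fixture(scope="session")
def worked_example():
    """The two-species hand-arithmetic plot: M=(100,200), RY_E=(1/2,1/2)."""
    monos = make_monos("s1", "control", 1, [100.0, 200.0])
    plot_a = make_plot_records("s1", "pA", 1, "control", [60.0, 120.0])
    plot_b = make_plot_records("s1", "pB", 1, "control", [70.0, 100.0])
    return monos, plot_a, plot_b


@pytest.fixture(scope="session")
def small_table():
    """Small species-level synthetic table (3 studies) plus its truth."""
    cfg = dp.SimulationConfig(
        n_studies=3, richness_levels=(1, 2, 4, 8), pool_size=8,
        plots_per_richness_per_treatment=1, n_years=2, seed=11)
    return dp.generate_experiment(cfg)


@pytest.fixture(scope="session")
def total_table():
    """Total-biomass-only synthetic table for productivity models."""
    cfg = dp.SimulationConfig(
        n_studies=4, richness_levels=(1, 2, 4, 8),
        plots_per_richness_per_treatment=2, n_years=3,
        species_level=False, seed=12)
    table, truth = dp.generate_experiment(cfg)
    return table, truth


def random_partition_instance(rng, n_species_max=5):
    """Random small mixture plot + matching monoculture table."""
    n = int(rng.integers(2, n_species_max + 1))
    means = rng.uniform(3.0, 300.0, n)
    props = rng.dirichlet(np.ones(n)) if rng.random() < 0.3 \
        else np.full(n, 1.0 / n)
    y_obs = rng.uniform(0.0, 1.5, n) * means
    monos = make_monos("s", "control", 1, means)
    plot = make_plot_records("s", "p", 1, "control", y_obs,
                             proportions=list(props))
    return plot, monos, means, props, y_obs
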