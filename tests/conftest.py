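"""Shared fixtures: one small synthetic NAM study reused across modules."""

import logging

import numpy as np
import pytest

import phenogs as pg

logging.getLogger("phenogs").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    return pg.SimulationConfig(
        n_families=6,
        lines_per_family=20,
        n_markers=400,
        n_chromosomes=4,
        n_environments=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """markers, genotype-level values, plots, reflectance, truth."""
    return pg.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_markers(small_study):
    return small_study[0]


@pytest.fixture(scope="session")
def small_grm(small_markers):
    return pg.compute_grm(pg.impute_missing(small_markers))


@pytest.fixture(scope="session")
def small_wide(small_study, small_markers):
    """Genotype x trait values for the first environment."""
    values = small_study[1]
    wide = values[values.environment == "E1"].pivot_table(
        index="genotype_id", columns="trait", values="value"
    )
    return wide.loc[small_markers.line_ids]


@pytest.fixture(scope="session")
def bivariate_study():
    """n=500, two traits with genetic correlation 0.7 and h2 (0.5, 0.8)."""
    cfg = pg.SimulationConfig(
        n_families=25,
        lines_per_family=20,
        n_markers=1000,
        n_chromosomes=10,
        n_environments=1,
        trait_names=("A", "B"),
        target_h2={"A": 0.5, "B": 0.8},
        genetic_corr=np.array([[1.0, 0.7], [0.7, 1.0]]),
        residual_corr=np.eye(2),
        seed=23,
    )
    markers = pg.simulate_nam_genotypes(cfg)
    table, truth = pg.simulate_traits(markers, cfg)
    grm = pg.compute_grm(pg.impute_missing(markers))
    wide = table.pivot_table(
        index="genotype_id", columns="trait", values="value"
    ).loc[markers.line_ids]
    return cfg, wide, grm, truth
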