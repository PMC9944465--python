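from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from kinact import (
    SimulationConfig,
    average_duplicates,
    fit_slope_table,
    generate_kinome_dataset,
    load_ptk_panel,
    log2_transform_slopes,
    qc_filter_peptides,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(seed=7, noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return generate_kinome_dataset(noiseless_config)


@pytest.fixture(scope="session")
def noiseless_matrix(noiseless_dataset):
    """Case-level activity matrix of the zero-noise default study."""
    intensity, _, truth = noiseless_dataset
    slopes = fit_slope_table(intensity)
    qc = qc_filter_peptides(slopes)
    retained = [p for p in slopes.index if p in qc.retained_peptides]
    activity = log2_transform_slopes(slopes.loc[retained])
    return average_duplicates(activity), truth


@pytest.fixture(scope="session")
def ptk_panel():
    """Shipped 36-peptide dual-source annotation snapshot + cluster labels."""
    return load_ptk_panel()


def small_config(**overrides) -> SimulationConfig:
    """A fast, reduced-size study for property tests."""
    base = dict(
        n_cases=8,
        n_peptides=24,
        n_flat_peptides=6,
        peptide_cluster_sizes=(6, 6, 6),
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)
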