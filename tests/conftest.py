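"""Shared fixtures: synthetic cohorts at fixed seeds, reused across modules."""

import dataclasses

import pytest

import vitrispec as v
from vitrispec.synth import SyntheticConfig, default_bands, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default study conditions, seed 0."""
    cfg = SyntheticConfig(seed=0)
    m, meta, truth = generate_cohort(cfg)
    return cfg, m, meta, truth


@pytest.fixture(scope="session")
def quiet_cohort():
    """Default band slopes, but all dispersions and artifacts off.

    Spectra are then deterministic functions of PMI -- the generator's own
    ground truth serves as the oracle.
    """
    bands = tuple(dataclasses.replace(b, sample_sd=0.0) for b in default_bands())
    cfg = SyntheticConfig(
        bands=bands,
        scatter_sd=0.0,
        baseline_offset_sd=0.0,
        baseline_slope_sd=0.0,
        replicate_noise_sd=0.0,
        seed=11,
    )
    m, meta, truth = generate_cohort(cfg)
    return cfg, m, meta, truth


@pytest.fixture()
def small_grid():
    return v.WavenumberGrid.regular(1800.0, 700.0, 2.0)


def y_known(meta):
    return {r.sample_id: r.pmi_hours for r in meta if r.cohort == "known"}


@pytest.fixture(scope="session")
def known_pmi():
    return y_known
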