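"""Shared fixtures: a small but complete synthetic system, reused via session scope."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from climdebt.config import SimulationConfig
from climdebt.synthetic import generate_infrastructure, simulate


def small_config(**overrides) -> SimulationConfig:
    """A reduced system that still exercises every pipeline stage."""
    base = dict(
        grid_nx=40,
        grid_ny=40,
        n_species=220,
        n_surveys_baseline=180,
        n_surveys_study=220,
        n_cluster_parents=12,
        cluster_sd=5000.0,
        warming_total=1.0,
        warming_profile="step",
        lag_lambda=0.5,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_system(small_cfg):
    """(landscape, surveys, truth) for the small configuration."""
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def small_infrastructure(small_cfg):
    return generate_infrastructure(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_matrix(n_surveys=200, n_species=40, breadth=1.5, seed=7):
    """A clean single-gradient community matrix for transfer-function tests.

    Species optima are spread along a temperature gradient; occupancy is
    Bernoulli of a Gaussian response.  Returns (CommunityMatrix, truth dict).
    """
    from climdebt.bioindication import CommunityMatrix

    r = np.random.default_rng(seed)
    x = np.linspace(5.0, 15.0, n_surveys)
    optima = np.linspace(4.0, 16.0, n_species)
    prob = 0.9 * np.exp(-0.5 * ((x[:, None] - optima[None, :]) / breadth) ** 2)
    mat = (r.random((n_surveys, n_species)) < prob).astype(float)
    # guarantee non-empty rows and occupied columns
    for i in range(n_surveys):
        if mat[i].sum() == 0:
            mat[i, np.argmin(np.abs(optima - x[i]))] = 1.0
    keep = mat.sum(axis=0) > 0
    mat = mat[:, keep]
    m = CommunityMatrix(
        mat,
        survey_ids=np.arange(n_surveys),
        species_ids=np.flatnonzero(keep),
        response=x,
    )
    return m, {"optima": optima[keep], "gradient": x}
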