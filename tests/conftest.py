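"""Shared fixtures: frozen study scenarios used across the suite.

The reduced scenarios scale the system down (fewer crypts, inflated mutation
rates, smaller capacities) so that stochastic ensembles are informative at
desk-scale run counts while preserving the model structure.
"""

import numpy as np
import pytest

import cryptevol as ce


@pytest.fixture(scope="session")
def default_params():
    return ce.ModelParams()


@pytest.fixture(scope="session")
def default_rates(default_params):
    return ce.conversion_matrix(default_params)


@pytest.fixture(scope="session")
def reduced_params():
    """Reduced system in the mean-field-valid regime: plentiful seeding
    (inflated APC hit rate), hazard carried by the large type-3 pool."""
    return ce.ModelParams(
        u=1.5e-4, mu=3e-9, n_crypt=1e3, K_A=2000.0, K_R=1000.0,
        gamma=(0.2, 0.12, 0.12, 1.01), delta6=0.0,
    )


@pytest.fixture(scope="session")
def rr_params():
    """Reduced system with earlier onset, for relative-risk ensembles."""
    return ce.ModelParams(
        u=1e-4, mu=5e-9, n_crypt=1e3, K_A=2000.0, K_R=1000.0,
        gamma=(0.25, 0.15, 0.15, 1.01), delta6=0.0,
    )


@pytest.fixture(scope="session")
def selection_truth():
    """Generating model for the model-selection study: inflated mutation
    rates (so the no-fission model has honest amplitude), no crypt death,
    tight capacities shaping the curve."""
    return ce.ModelParams(
        u=1e-4, mu=1e-8, n_crypt=1e3, delta=0.0, K_A=500.0, K_R=250.0,
        gamma=(0.5, 0.35, 0.35, 1.01),
    )


@pytest.fixture(scope="session")
def midpoint_ages():
    return np.array([57.5, 62.5, 67.5, 72.5, 77.5])
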