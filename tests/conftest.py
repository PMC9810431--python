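"""Shared fixtures: printed parameter regimes and the screening sweep."""

import numpy as np
import pytest

from opposer.models import RateParameters
from opposer.sweep import SamplingSpec, sample_parameters, run_sweep

#: seed of the screening ensemble used across the acceptance tests
SWEEP_SEED = 1
SWEEP_N = 5000


@pytest.fixture(scope="session")
def fig5_params() -> RateParameters:
    """The introductory two-cycle regime (also figures 3 and 6)."""
    return RateParameters(
        k_A1=200, k_A2=200, k_B1=10, k_B2=4,
        K_A1=1, K_A2=1, K_B1=0.01, K_B2=0.01,
        A_tot=10, B_tot=10, E_tot=1,
    )


@pytest.fixture(scope="session")
def fig4_params() -> RateParameters:
    """High-abundance regime with a well-resolved adaptation band."""
    return RateParameters(
        k_A1=200, k_A2=200, k_B1=10, k_B2=4,
        K_A1=1, K_A2=1, K_B1=0.01, K_B2=0.01,
        A_tot=200, B_tot=200, E_tot=1,
    )


@pytest.fixture(scope="session")
def screening_sweep():
    """The full screening sweep: 5000 log-uniform parameter sets assessed
    with both model variants on the default 40-point input grid."""
    ensemble = sample_parameters(SamplingSpec(n_sets=SWEEP_N, seed=SWEEP_SEED))
    return run_sweep(ensemble, tqssa=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230104)
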