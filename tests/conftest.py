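import numpy as np
import pytest

from gliosurv.cohort import GeneratorConfig, generate_cohort
from gliosurv.pi_model import DeltaRInverter
import gliosurv.pihna as pihna


@pytest.fixture(scope="session")
def inverter() -> DeltaRInverter:
    """Moderate-resolution D/rho inversion table shared across tests."""
    return DeltaRInverter.build(n_grid=24)


@pytest.fixture(scope="session")
def small_library() -> pihna.SimulationLibrary:
    """A coarse 4x4 forward-simulation library for unit-level checks."""
    return pihna.build_library(
        np.geomspace(3.0, 100.0, 4), np.geomspace(5.0, 100.0, 4)
    )


@pytest.fixture(scope="session")
def default_library() -> pihna.SimulationLibrary:
    """The default-resolution library used for the recovery experiments."""
    Dg, rg = pihna.default_parameter_grids(16)
    return pihna.build_library(Dg, rg)


@pytest.fixture(scope="session")
def synthetic_cohort_494():
    """One default-size synthetic cohort (seeded, reused read-only)."""
    return generate_cohort(GeneratorConfig(n=494, seed=11))


def null_generator_config(n: int, seed: int) -> GeneratorConfig:
    """Generator config with every log-hazard zero: survival independent
    of all covariates (the null construction for calibration checks)."""
    cfg = GeneratorConfig(n=n, seed=seed)
    cfg.distributions.male.hazard_terms = []
    cfg.distributions.female.hazard_terms = []
    return cfg
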