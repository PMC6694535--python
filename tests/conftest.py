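import numpy as np
import pytest

from cvdsim.cli_io import ModelConfig
from cvdsim.demography import DemographyInputs
from cvdsim.grids import GRID_SHAPE, CohortGrid
from cvdsim.synthetic_data import calibrated_fixture, make_singapore_like_fixture


@pytest.fixture
def config():
    return ModelConfig()


@pytest.fixture
def flat_inputs():
    """Small, flat demographic inputs: uniform population, low constant mortality."""
    n = 40
    pop = CohortGrid.filled(100.0)
    fert = np.full(n, 0.03)
    mort = np.full((n,) + GRID_SHAPE, 0.01)
    mig = np.zeros((n,) + GRID_SHAPE)
    return DemographyInputs(pop, 2010, fert, mort, mig)


@pytest.fixture(scope="session")
def fixture_sg():
    """The Singapore-like synthetic fixture (uncalibrated intercepts)."""
    return make_singapore_like_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_calibrated():
    fix, report = calibrated_fixture(seed=0)
    return fix


@pytest.fixture(scope="session")
def scenario_results(fixture_calibrated):
    """All five built-in scenarios run once on the calibrated fixture."""
    from cvdsim.experiments import builtin_scenarios, run_scenario

    fix = fixture_calibrated
    return {
        name: run_scenario(spec, fix.inputs, fix.state, fix.config)
        for name, spec in builtin_scenarios(fix.config).items()
    }
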