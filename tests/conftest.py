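from pathlib import Path

import pandas as pd
import pytest

import co2resp as cr

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_effects():
    return cr.load_reference_effects()


@pytest.fixture(scope="session")
def levels():
    return cr.default_factor_levels()


def load_grid(name: str) -> pd.DataFrame:
    """Published reference grid (long form: spectrum, intensity, co2, value)."""
    return pd.read_csv(DATA / name)


@pytest.fixture(scope="session")
def default_truth(reference_effects):
    return cr.SimulationTruth(seed=1)


@pytest.fixture(scope="session")
def simulated_default(default_truth):
    """One full default simulation (10 spectra x 3 plants x 168 readings)."""
    return cr.simulate_experiment(default_truth)


@pytest.fixture(scope="session")
def fitted_default(simulated_default):
    """ML fit of the default simulation, shared across tests."""
    return cr.fit_model(simulated_default, cr.FitConfig(maxiter=5000))
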