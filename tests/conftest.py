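import numpy as np
import pytest

from stochdea import (EcosystemDataset, FixtureConfig, ScenarioSpec,
                      default_scenarios, generate_ecosystem)
from stochdea.dataset import parse_variable_name


@pytest.fixture(scope="session")
def eco() -> EcosystemDataset:
    """Default 19 x 57 synthetic ecosystem (shared, read-only)."""
    return generate_ecosystem(FixtureConfig(seed=42))


@pytest.fixture(scope="session")
def scenarios(eco):
    return default_scenarios(eco)


@pytest.fixture
def tiny_dataset() -> EcosystemDataset:
    """3 areas x 4 variables with real taxonomy names (2 inputs, 2 outputs)."""
    names = ["TD1", "ProfTotO8+O10", "UD1", "UFrecO8+O10"]
    return EcosystemDataset(
        dmu_names=["A", "B", "C"],
        variables=[parse_variable_name(n) for n in names],
        values=np.array([
            [1.0, 10.0, 50.0, 400.0],
            [2.0, 12.0, 60.0, 500.0],
            [0.5, 8.0, 40.0, 300.0],
        ]),
    )


@pytest.fixture
def tiny_scenario() -> ScenarioSpec:
    return ScenarioSpec(
        id="T1",
        label="tiny",
        input_vars=("TD1", "ProfTotO8+O10"),
        output_vars=("UD1", "UFrecO8+O10"),
    )
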