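import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from searchshare import SimulationConfig

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def wide_csv(tmp_path):
    """Write a wide-dialect panel CSV and return its path."""

    def make(rows, columns, name="panel.csv"):
        path = tmp_path / name
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
        return path

    return make


def base_sim_config(**overrides) -> SimulationConfig:
    """Small three-symptom configuration used across test modules."""
    kwargs = dict(
        n_counties=8,
        n_periods=3,
        symptom_classes={"anx": "broad", "adhd": "specific", "cough": "non_mh"},
        base_propensity={"anx": 2.0, "adhd": 3.0, "cough": 5.0},
        fraction_shortage=0.5,
        fraction_rural=0.25,
        fraction_micropolitan=0.25,
        seed=7,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture
def sim_config():
    return base_sim_config
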