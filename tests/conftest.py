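import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from barnsense.scenarios import dairy_scenario
from barnsense.synthetic_barn import GroundTruth, truth_from_scenario

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_constant_truth(values: dict, n: int = 720, zone: str = "z",
                        start: str = "2023-01-01") -> GroundTruth:
    """A ground truth whose channels are flat at the given values."""
    index = pd.date_range(start, periods=n, freq="10s")
    df = pd.DataFrame({ch: np.full(n, float(v)) for ch, v in values.items()},
                      index=index)
    return GroundTruth(zones={zone: df}, params={"constant": values}, seed=0)


@pytest.fixture(scope="session")
def dairy():
    """One-day steady dairy scenario with its (seed-0) ground truth."""
    scenario = dairy_scenario(duration_days=1)
    truth = truth_from_scenario(scenario, seed=0, initial="steady")
    return scenario, truth
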