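import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from antegress import EgressSeries, ExperimentDataset, SimulationConfig, simulate_experiment

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset() -> ExperimentDataset:
    """Full synthetic design (6 widths x 6 repellent + 3 control reps), seed 0."""
    return simulate_experiment(SimulationConfig(seed=0))


@pytest.fixture()
def three_trial_dataset() -> ExperimentDataset:
    series = (
        EgressSeries("t1", "repellent", 0.5, 30, np.array([0.0, 1.2, 3.0])),
        EgressSeries("t2", "repellent", 1.0, 30, np.array([0.0, 0.5])),
        EgressSeries("t3", "control", 0.5, 30, np.array([0.0])),
    )
    return ExperimentDataset(series=series, provenance="fixture")


def random_series(rng: np.random.Generator, max_events: int = 12) -> EgressSeries:
    """A small random trial for oracle comparisons."""
    k = int(rng.integers(0, max_events + 1))
    if k == 0:
        times = np.empty(0)
    else:
        gaps = rng.choice([0.0, 0.5, 1.0, 1.5, 2.0, 5.0], size=k - 1)
        times = np.concatenate([[0.0], np.cumsum(gaps)])
    return EgressSeries("rand", "repellent", 1.0, max(k, 1), times)
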