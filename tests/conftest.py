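import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ernet.connectivity import ConnectivityMatrix, correlation_matrix
from ernet.parcellation import ParcellationSpec, bundled_parcellation
from ernet.simulate import SimulationConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def power_spec() -> ParcellationSpec:
    return bundled_parcellation()


@pytest.fixture()
def toy_spec() -> ParcellationSpec:
    """6-node toy parcellation with two 3-node subnetworks."""
    df = pd.DataFrame({
        "node_id": [1, 2, 3, 4, 5, 6],
        "x": [0, 1, 2, 3, 4, 5], "y": [0] * 6, "z": [0] * 6,
        "network": ["A", "A", "A", "B", "B", "B"],
    })
    return ParcellationSpec(df, expected_sizes={"A": 3, "B": 3})


@pytest.fixture(scope="session")
def small_cohort():
    """12-participant default-condition cohort with the injected FPN effect."""
    config = SimulationConfig(n_participants=12, seed=20260926)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort_matrices(small_cohort):
    return [correlation_matrix(ts) for ts in small_cohort.timeseries]


def constant_matrix(n: int, z: float, node_ids=None) -> ConnectivityMatrix:
    m = np.full((n, n), float(z))
    np.fill_diagonal(m, 0.0)
    return ConnectivityMatrix(m, node_ids or tuple(range(1, n + 1)))
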