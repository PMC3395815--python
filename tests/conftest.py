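import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from larvataxis import AISeries, AssayConfig, Dataset, reference_data, simulate_dynamics


@pytest.fixture(scope="session")
def reference():
    """The embedded experimental intensity table and published (alpha, beta)."""
    table, params = reference_data()
    return table, params


@pytest.fixture(scope="session")
def noiseless_550(reference):
    """Exact 22-point model AI series at 550 lux on the half-minute grid."""
    _, params = reference
    _, series = simulate_dynamics(
        params, AssayConfig(intensity=550.0, seed=0), noise=False
    )
    return Dataset(observations=series, intensity=550.0)
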