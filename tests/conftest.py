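import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nichefab.synth import ForwardModelParams, gen_calibration

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_calibration():
    """Compact noisy calibration table + its noiseless forward model."""
    return gen_calibration(
        ForwardModelParams(noise_cv=0.05, seed=11),
        pegpi_levels=np.linspace(10, 90, 9),
        focus_levels=np.linspace(0, 4, 7),
        conjugate_levels=(0.0, 2.0),
    )


@pytest.fixture(scope="session")
def default_calibration():
    """Full default calibration grid used for end-to-end recovery checks."""
    return gen_calibration(ForwardModelParams(seed=1))


@pytest.fixture(scope="session")
def noiseless_calibration():
    return gen_calibration(
        ForwardModelParams(noise_cv=0.0, seed=0),
        pegpi_levels=np.linspace(10, 90, 9),
        focus_levels=np.linspace(0, 4, 7),
        conjugate_levels=(0.0,),
    )
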