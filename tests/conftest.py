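import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    from firesavanna.vegmodel import ModelParams

    return ModelParams()


@pytest.fixture(scope="session")
def reference_model():
    from firesavanna.suitability import SuitabilityModel

    return SuitabilityModel.reference()


@pytest.fixture(autouse=True)
def _quiet_stability_warnings():
    """The shipped defaults intentionally trip the worst-case outflow
    warning (clipping handles it); keep test output readable."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="dt \\* worst-case outflow",
                                category=RuntimeWarning)
        yield
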