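import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mainseq.models import DurationILLogisticModel, VelocityModelParams
from mainseq.params import load_param_set

settings.register_profile(
    "ci", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MICRO_SETS = ("fixation-500hz-microsaccades", "fixation-300hz-microsaccades", "free-viewing-microsaccades")
ALL_SCATTER_SETS = MICRO_SETS + ("free-viewing-saccades", "free-viewing-combined")


@pytest.fixture(scope="session")
def exp1():
    """Aggregate fit bundle for the 500 Hz fixation microsaccade data set."""
    return load_param_set("fixation-500hz-microsaccades")


@pytest.fixture(scope="session")
def saccade_set():
    return load_param_set("free-viewing-saccades")


@pytest.fixture(scope="session")
def combined_set():
    return load_param_set("free-viewing-combined")


@pytest.fixture(scope="session")
def classic():
    """Classical literature reference: Baloh affine law and matching curves."""
    return load_param_set("classic-reference")


@pytest.fixture(scope="session")
def classic_duration(classic) -> DurationILLogisticModel:
    """Inverse-linear logistic duration law on the millisecond scale."""
    return classic.duration_model()
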