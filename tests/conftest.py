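import numpy as np
import pytest

from catabarrier.cohort_synthesis import GeneratorConfig, generate_cohort
from catabarrier.model_core import ModelParams, compute_barrier
from catabarrier.registry import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def baseline():
    return ModelParams.baseline()


@pytest.fixture(scope="session")
def baseline_barrier(baseline):
    return compute_barrier(baseline)


@pytest.fixture(scope="session")
def cohort(registry):
    """Default-config cohort at a fixed seed, shared across tests."""
    subjects, report = generate_cohort(GeneratorConfig(seed=1), registry)
    return subjects, report
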