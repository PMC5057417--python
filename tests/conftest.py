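import numpy as np
import pandas as pd
import pytest

from cphtriage.cohort import GeneratorConfig, generate_cohort
from cphtriage.triage import default_cta_chart


@pytest.fixture(scope="session")
def chart():
    return default_cta_chart()


@pytest.fixture(scope="session")
def small_cohort():
    """20k-encounter synthetic cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(n=20_000, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """200k-encounter cohort for parameter-recovery checks."""
    return generate_cohort(GeneratorConfig(n=200_000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
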