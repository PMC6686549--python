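import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from medgwg.anthropometry import derive_analysis_rows
from medgwg.lms import synthetic_lms_table
from medgwg.synthetic import GeneratorConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lms():
    return synthetic_lms_table()


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=20240601)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One pristine default-size cohort, shared across tests."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def analysis_rows(cohort, lms):
    rows, _ = derive_analysis_rows(cohort.mothers, cohort.growth, lms)
    return rows


@pytest.fixture()
def small_config():
    return dataclasses.replace(
        GeneratorConfig(seed=11), n_pairs=250,
        glitch_rate=0.0, missing_rate={})


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
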