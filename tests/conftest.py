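import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mrkit.datasets import load_igf1_harmonized
from mrkit.scenarios import continuous_config
from mrkit.simulate import simulate_cohort


@pytest.fixture(scope="session")
def hip_harmonized():
    return load_igf1_harmonized("hip")


@pytest.fixture(scope="session")
def knee_harmonized():
    return load_igf1_harmonized("knee")


@pytest.fixture(scope="session")
def continuous_cohort():
    """One medium continuous-outcome cohort shared by estimator tests."""
    return simulate_cohort(continuous_config(50_000, seed=42))


@pytest.fixture(scope="session")
def snp_ids(continuous_cohort):
    return [s.snp_id for s in continuous_cohort.truth.config.snps]
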