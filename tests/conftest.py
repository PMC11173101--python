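import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rocoloop import PKParameterSet, PDParameterSet, nominal_pk_for_weight, default_pd

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def wierda() -> PKParameterSet:
    """Weight-scaled nominal PK set for a 63-kg subject."""
    return nominal_pk_for_weight(63.0)


@pytest.fixture(scope="session")
def pd_pop() -> PDParameterSet:
    """Population PD parameters with monitor noise enabled."""
    return default_pd()


@pytest.fixture(scope="session")
def pd_clean() -> PDParameterSet:
    """Noise-free population PD parameters."""
    return default_pd(noise_sd=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240527)


def random_params(gen: np.random.Generator) -> PKParameterSet:
    """Random plausible parameter set for randomized equivalence checks."""
    return PKParameterSet(
        v1=float(gen.uniform(1.0, 6.0)),
        k10=float(gen.uniform(0.02, 0.3)),
        k12=float(gen.uniform(0.0, 0.4)),
        k21=float(gen.uniform(0.01, 0.4)),
        k13=float(gen.uniform(0.0, 0.1)),
        k31=float(gen.uniform(0.005, 0.1)),
        ke0=float(gen.uniform(0.05, 0.5)),
        label="randomized",
    )
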