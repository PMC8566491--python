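import numpy as np
import pytest

from oralflow import (
    OralParameters,
    PowerLawFluid,
    default_oral_parameters,
    table1_samples,
)


@pytest.fixture(scope="session")
def defaults() -> OralParameters:
    return default_oral_parameters()


@pytest.fixture(scope="session")
def table1():
    return table1_samples()


@pytest.fixture(scope="session")
def sample1_fluid() -> PowerLawFluid:
    return PowerLawFluid(kappa=0.026, n=0.55, label="1")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
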