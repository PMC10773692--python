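import numpy as np
import pytest

from pebwe import load_dataset

VALID_BETAS = (0.1, 0.5, 0.8, 0.9, 1.2, 1.5, 1.8)


@pytest.fixture(scope="session")
def covid_counts() -> np.ndarray:
    return load_dataset("covid_china").sample


@pytest.fixture(scope="session")
def leukemia_sample():
    return load_dataset("leukemia_remission").sample


@pytest.fixture(scope="session")
def pelvic_sample():
    return load_dataset("pelvic_tumor").sample
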