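import numpy as np
import pytest

from itrcapture.fusion_detection import AlignParams
from itrcapture.synthetic_data import attach_itr_primer, make_toy_host, make_toy_locus
from itrcapture.vector_model import aav_lambda_465


@pytest.fixture(scope="session")
def vector():
    return aav_lambda_465()


@pytest.fixture(scope="session")
def primed_vector():
    return attach_itr_primer(aav_lambda_465())


@pytest.fixture(scope="session")
def locus():
    return make_toy_locus()


@pytest.fixture(scope="session")
def params():
    return AlignParams()


@pytest.fixture(scope="session")
def toy_host():
    return make_toy_host(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20190930)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))
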