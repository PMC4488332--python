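import numpy as np
import pytest

from snpherit import make_kinship, sample_scores, build_grm


@pytest.fixture(scope="session")
def identity_kinship_small():
    return make_kinship(6, 0.0, 0.0, seed=0)


@pytest.fixture(scope="session")
def related_kinship():
    return make_kinship(120, 0.0, 0.05, seed=11)


@pytest.fixture(scope="session")
def small_grm(related_kinship):
    Z = sample_scores(120, 400, related_kinship, seed=21)
    return build_grm(Z)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
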