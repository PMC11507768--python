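import numpy as np
import pytest

from jple import core, synthetic
from jple.io import KmerMatrix


@pytest.fixture(scope="session")
def small_fixture():
    """A small planted cohort: 4 families x 4 members, noise sd 0.1."""
    fx = synthetic.gen_families(4, 4, seed=11)
    pm = synthetic.gen_planted_model(fx, noise_sd=0.1, seed=11)
    R = synthetic.gen_profiles(fx, pm)
    P = fx.peptide_matrix()
    return fx, pm, P, R


@pytest.fixture(scope="session")
def small_model(small_fixture):
    _, _, P, R = small_fixture
    return core.fit(P, R)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_matrices(rng, n=10, p=20, r=15):
    """Random raw training blocks with guaranteed column variance."""
    P = KmerMatrix(
        [f"r{i}" for i in range(n)],
        [f"p{j}" for j in range(p)],
        rng.normal(size=(n, p)),
    )
    R = KmerMatrix(
        [f"r{i}" for i in range(n)],
        [f"k{j}" for j in range(r)],
        rng.normal(size=(n, r)),
    )
    return P, R
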