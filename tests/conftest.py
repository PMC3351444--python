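import numpy as np
import pytest

import pepgnn as pg


@pytest.fixture(scope="session")
def alphabet():
    return pg.default_alphabet()


@pytest.fixture(scope="session")
def small_alphabet():
    """Six residue types (one D) — keeps finite-difference checks cheap."""
    return pg.Alphabet.from_pairs(
        [("A", "L"), ("C", "L"), ("D", "L"), ("E", "L"), ("F", "L"), ("F", "D")]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_peptide(alphabet, length, rng):
    return pg.Peptide(alphabet, rng.integers(0, alphabet.size, size=length))


def random_model(alphabet, rng, N=None, T=None, activation=None, output_mode=None, scale=0.5):
    N = int(rng.integers(0, 4)) if N is None else N
    T = int(rng.integers(1, 6)) if T is None else T
    activation = activation or ["tanh", "logistic", "identity"][int(rng.integers(3))]
    output_mode = output_mode or ["average", "sum"][int(rng.integers(2))]
    return pg.init_model(
        alphabet, N, T, seed=int(rng.integers(2**31)),
        activation=activation, output_mode=output_mode, scale=scale,
    )
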