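import numpy as np
import pytest

from wseqkernel.matrices import (
    AminoAlphabet,
    CholeskyFactor,
    SubstitutionMatrix,
    bl62,
    hadamard_power,
)
from wseqkernel.string_kernel import SequenceRecord


@pytest.fixture(scope="session")
def bl62_matrix():
    return bl62()


@pytest.fixture(scope="session")
def bl62_02(bl62_matrix):
    return hadamard_power(bl62_matrix, 0.2)


@pytest.fixture
def ab2():
    return AminoAlphabet(("A", "C"))


@pytest.fixture
def ab3():
    return AminoAlphabet(("A", "C", "D"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_pd_matrix(alphabet, rng, nonneg=True):
    """Random PD matrix via L L^T with diagonal bounded away from zero."""
    n = len(alphabet)
    L = np.tril(rng.normal(size=(n, n)))
    np.fill_diagonal(L, np.abs(np.diag(L)) + 0.5)
    values = L @ L.T
    if nonneg:
        values = np.abs(values)
        # |L L^T| may lose PD; re-symmetrize through its own factor if needed
        ev = np.linalg.eigvalsh(values)
        if ev[0] <= 0:
            values = values + (abs(ev[0]) + 0.1) * np.eye(n)
    return SubstitutionMatrix(alphabet, values)


def random_sequence(alphabet, rng, length):
    letters = list(alphabet.letters)
    return SequenceRecord(
        f"seq{rng.integers(1 << 30)}", "".join(rng.choice(letters, size=length)), alphabet
    )


@pytest.fixture
def identity2(ab2):
    return SubstitutionMatrix(ab2, np.eye(2), "I2")


@pytest.fixture
def identity_factor():
    from wseqkernel.matrices import CANONICAL_ALPHABET

    return CholeskyFactor(CANONICAL_ALPHABET, np.eye(20))
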