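import numpy as np
import pytest

from revgwas.io_model import BinaryMatrix


def make_pair(rng, M, N, P, px=0.3, py=0.4):
    """Random aligned genotype/phenotype matrices for property tests."""
    X = BinaryMatrix(
        (rng.random((M, N)) < px).astype(np.int8),
        tuple(f"s{i}" for i in range(M)),
        tuple(f"snp{j}" for j in range(N)),
        kind="genotype",
    )
    Y = BinaryMatrix(
        (rng.random((M, P)) < py).astype(np.int8),
        tuple(f"s{i}" for i in range(M)),
        tuple(f"ph{j}" for j in range(P)),
        kind="phenotype",
    )
    return X, Y


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
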