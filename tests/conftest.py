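import numpy as np
import pytest

from codonexpress import ALL_CODONS, CodingSequence


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_coding_sequence(rng, n_codons: int, ident: str = "seq") -> CodingSequence:
    codons = [ALL_CODONS[i] for i in rng.integers(0, 64, size=n_codons)]
    return CodingSequence(ident, "".join(codons))


@pytest.fixture
def linear_dataset(rng):
    """Noiseless y = Xw on a small dense matrix (all 5 columns informative)."""
    X = rng.normal(size=(40, 5))
    w = np.array([1.5, -2.0, 0.5, 3.0, -1.0])
    y = X @ w
    return X, y, w
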