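import numpy as np
import pytest

import protgram as pg


@pytest.fixture
def small_corpus() -> pg.CleanCorpus:
    return pg.CleanCorpus(sequences=["ACAC", "CAAC", "ACCA"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_corpus(rng: np.random.Generator, alphabet: str = "ACDEF",
                  n_sequences: int = 20, min_len: int = 5, max_len: int = 30) -> pg.CleanCorpus:
    """A small random corpus over a reduced residue alphabet."""
    seqs = []
    symbols = list(alphabet)
    for _ in range(n_sequences):
        length = int(rng.integers(min_len, max_len + 1))
        seqs.append("".join(rng.choice(symbols, size=length)))
    return pg.CleanCorpus(sequences=seqs)


def random_stochastic(rng: np.random.Generator, n: int) -> np.ndarray:
    m = rng.random((n, n)) + 1e-3
    return m / m.sum(axis=1, keepdims=True)
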