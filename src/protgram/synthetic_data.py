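"""Synthetic corpora and PPI datasets with known statistical structure.

Two generators make every pipeline stage testable without external
downloads:

* :func:`sample_corpus` draws residue sequences from a known first-order
  Markov chain, emulating the view of protein sequences as random walks on
  a source graph of residues.  The empirical level-1 transition matrix of
  the resulting corpus converges to the generating chain.
* :func:`sample_ppi` plants a sequence-detectable interaction signal:
  proteins belong to families, each family has its own residue chain
  (a perturbation of a common base chain, with a single mixing dial
  controlling separation), and a pair interacts with a probability that
  depends only on the family pair.  With separated chains and a contrasted
  interaction matrix, sequence-derived embeddings suffice to predict the
  labels; with a constant interaction matrix the dataset is a null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus_io import AMINO_ACIDS, CleanCorpus, DEFAULT_SEPARATOR, PairTable

logger = logging.getLogger("protgram")


class SpecError(ValueError):
    """Raised for an invalid generator specification."""


def _check_stochastic(matrix: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise SpecError(f"{name} must be square")
    if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
        raise SpecError(f"{name} must be row-stochastic (rows summing to 1)")
    return m


@dataclass
class GeneratorSpec:
    """A first-order Markov sequence generator over a residue alphabet."""

    alphabet: str
    transition: np.ndarray
    initial: np.ndarray | None = None
    n_sequences: int = 100
    length: int | tuple[int, int] = (100, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.alphabet) < 2:
            raise SpecError("alphabet must have at least 2 symbols")
        if not set(self.alphabet) <= set(AMINO_ACIDS):
            raise SpecError("alphabet must be a subset of the 20 standard residues")
        self.transition = _check_stochastic(self.transition, "transition matrix")
        if self.transition.shape[0] != len(self.alphabet):
            raise SpecError("transition matrix size must match the alphabet")
        if self.initial is None:
            self.initial = np.full(len(self.alphabet), 1.0 / len(self.alphabet))
        self.initial = np.asarray(self.initial, dtype=float)
        if self.initial.shape != (len(self.alphabet),) or not np.isclose(self.initial.sum(), 1.0):
            raise SpecError("initial distribution must sum to 1 over the alphabet")


def _sample_lengths(length, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(length, int):
        return np.full(n, length, dtype=int)
    lo, hi = length
    return rng.integers(lo, hi + 1, size=n)


def _walk(chain_cum: np.ndarray, init_cum: np.ndarray, length: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(length)
    states = np.empty(length, dtype=int)
    states[0] = np.searchsorted(init_cum, u[0], side="right")
    for j in range(1, length):
        states[j] = np.searchsorted(chain_cum[states[j - 1]], u[j], side="right")
    return states


def sample_corpus(spec: GeneratorSpec) -> CleanCorpus:
    """Sample a corpus of Markov-chain sequences; deterministic under seed."""
    rng = np.random.default_rng(spec.seed)
    chain_cum = np.cumsum(spec.transition, axis=1)
    init_cum = np.cumsum(spec.initial)
    symbols = np.array(list(spec.alphabet))
    lengths = _sample_lengths(spec.length, spec.n_sequences, rng)
    seqs = ["".join(symbols[_walk(chain_cum, init_cum, L, rng)]) for L in lengths]
    return CleanCorpus(sequences=seqs, separator=DEFAULT_SEPARATOR,
                       source_path=f"synthetic:markov(seed={spec.seed})",
                       ids=[f"S{i:05d}" for i in range(len(seqs))])


def make_family_chains(
    alphabet_size: int, n_families: int, mixing: float = 0.6, seed: int = 0
) -> list[np.ndarray]:
    """Family chains as perturbations of a common base chain.

    Each family chain is ``(1 - mixing) * uniform + mixing * P_k`` with
    ``P_k`` a family-specific random permutation matrix, so ``mixing`` is
    the single dial for signal strength: rows of two family chains that
    disagree on the preferred successor are at total-variation distance
    exactly ``mixing``.
    """
    if not 0.0 <= mixing <= 1.0:
        raise SpecError("mixing must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base = np.full((alphabet_size, alphabet_size), 1.0 / alphabet_size)
    chains = []
    for _ in range(n_families):
        perm = np.eye(alphabet_size)[rng.permutation(alphabet_size)]
        chains.append((1.0 - mixing) * base + mixing * perm)
    return chains


@dataclass
class PlantedPPISpec:
    """A family-structured PPI dataset with a planted interaction signal."""

    family_chains: list[np.ndarray]
    interaction_probs: np.ndarray
    alphabet: str = AMINO_ACIDS
    proteins_per_family: int = 100
    n_pairs: int = 2000
    length: int | tuple[int, int] = (100, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        self.family_chains = [
            _check_stochastic(c, f"family chain {k}") for k, c in enumerate(self.family_chains)
        ]
        p = np.asarray(self.interaction_probs, dtype=float)
        nf = len(self.family_chains)
        if p.shape != (nf, nf):
            raise SpecError("interaction matrix shape must match the number of families")
        if (p < 0).any() or (p > 1).any():
            raise SpecError("interaction probabilities must lie in [0, 1]")
        if not np.allclose(p, p.T):
            raise SpecError("interaction matrix must be symmetric")
        self.interaction_probs = p
        if np.ptp(p) == 0:
            warnings.warn("interaction matrix is constant: no learnable signal", stacklevel=2)

    @property
    def n_families(self) -> int:
        return len(self.family_chains)

    @classmethod
    def two_family(
        cls,
        within: float = 0.9,
        cross: float = 0.1,
        proteins_per_family: int = 100,
        n_pairs: int = 2000,
        mixing: float = 0.6,
        alphabet: str = AMINO_ACIDS,
        length: int | tuple[int, int] = (100, 300),
        seed: int = 0,
    ) -> "PlantedPPISpec":
        """The canonical two-family benchmark configuration."""
        chains = make_family_chains(len(alphabet), 2, mixing=mixing, seed=seed)
        probs = np.array([[within, cross], [cross, within]])
        return cls(family_chains=chains, interaction_probs=probs, alphabet=alphabet,
                   proteins_per_family=proteins_per_family, n_pairs=n_pairs,
                   length=length, seed=seed)


def sample_ppi(spec: PlantedPPISpec) -> tuple[CleanCorpus, PairTable, np.ndarray]:
    """Sample protein sequences and a labeled pair table.

    Each protein's sequence is drawn from its family chain; each sampled
    unordered pair (without replacement) is labeled 1 with the family-pair
    interaction probability.  Returns (corpus with protein ids, pair table,
    per-protein family assignment).
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_families * spec.proteins_per_family
    families = np.repeat(np.arange(spec.n_families), spec.proteins_per_family)
    symbols = np.array(list(spec.alphabet))
    k = len(spec.alphabet)
    init_cum = np.cumsum(np.full(k, 1.0 / k))
    chain_cums = [np.cumsum(c, axis=1) for c in spec.family_chains]

    lengths = _sample_lengths(spec.length, n_total, rng)
    ids = [f"F{families[i]}P{i:05d}" for i in range(n_total)]
    seqs = [
        "".join(symbols[_walk(chain_cums[families[i]], init_cum, lengths[i], rng)])
        for i in range(n_total)
    ]
    corpus = CleanCorpus(sequences=seqs, separator=DEFAULT_SEPARATOR,
                         source_path=f"synthetic:planted_ppi(seed={spec.seed})", ids=ids)

    max_pairs = n_total * (n_total - 1) // 2
    if spec.n_pairs > max_pairs:
        raise SpecError(f"n_pairs={spec.n_pairs} exceeds the {max_pairs} possible pairs")
    iu, ju = np.triu_indices(n_total, k=1)
    chosen = rng.choice(max_pairs, size=spec.n_pairs, replace=False)
    ia, ib = iu[chosen], ju[chosen]
    p = spec.interaction_probs[families[ia], families[ib]]
    labels = (rng.random(spec.n_pairs) < p).astype(int)
    table = PairTable(pairs=pd.DataFrame({
        "id_a": [ids[i] for i in ia],
        "id_b": [ids[j] for j in ib],
        "label": labels,
    }), id_space="synthetic")
    pos, neg = table.class_counts()
    logger.info("planted PPI dataset: %d positives / %d negatives", pos, neg)
    return corpus, table, families
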