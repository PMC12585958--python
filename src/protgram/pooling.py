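"""Mean-context attention pooling of n-gram embeddings into protein vectors.

The pooling is parameter-free: the context vector c is the mean of the
input vectors, each vector is scored by its dot product with c, the scores
pass through a softmax, and the pooled vector is the attention-weighted sum.
Every sliding n-gram window of a protein contributes one vector (windows,
not unique types), so repeated motifs weigh in proportionally.  PCA to a
standard dimension (64 by default) aligns the feature space with other
embedding methods before pair classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger("protgram")

PCA_TARGET_DIM = 64


class PoolingError(ValueError):
    """Raised when there is nothing to pool."""


@dataclass
class EmbeddingTable:
    """Mapping n-gram string -> embedding vector, stored as vocab + matrix."""

    vocab: list[str]
    vectors: np.ndarray  # (len(vocab), d)
    level: int

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocab):
            raise ValueError("vocab / vectors length mismatch")
        self.index = {g: i for i, g in enumerate(self.vocab)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, gram: str) -> bool:
        return gram in self.index

    def __getitem__(self, gram: str) -> np.ndarray:
        return self.vectors[self.index[gram]]

    def save_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for g, v in zip(self.vocab, self.vectors):
                fh.write(g + "\t" + "\t".join(f"{x:.10g}" for x in v) + "\n")

    @classmethod
    def load_tsv(cls, path: str, level: int) -> "EmbeddingTable":
        vocab, rows = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                vocab.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(vocab=vocab, vectors=np.asarray(rows), level=level)


@dataclass
class PooledProtein:
    """A protein's pooled embedding with its attention trace."""

    protein_id: str
    vector: np.ndarray
    attention: list[tuple[int, str, float]]  # (window position, n-gram, weight)
    coverage: float


def attention_pool(vectors: np.ndarray | list) -> tuple[np.ndarray, np.ndarray]:
    """Pool a non-empty list of d-vectors by mean-context attention.

    Returns (pooled vector, attention weights); weights are non-negative and
    sum to 1.  Identical inputs receive uniform weights and pool to
    themselves; the pooled vector always lies in the convex hull of the
    inputs.
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if v.size == 0:
        raise PoolingError("cannot pool an empty list of vectors")
    c = v.mean(axis=0)
    s = v @ c
    s = s - s.max()  # stabilized softmax
    w = np.exp(s)
    alpha = w / w.sum()
    return alpha @ v, alpha


def protein_embedding(
    sequence: str,
    table: EmbeddingTable,
    n: int,
    protein_id: str = "",
) -> PooledProtein:
    """Pool a cleaned protein sequence's n-gram window embeddings.

    Every length-n window is looked up in ``table``; windows absent from the
    vocabulary are skipped and counted against ``coverage``.  A protein with
    no known window gets a zero vector, coverage 0, and a logged warning.
    """
    if n != table.level:
        raise ValueError(f"table level {table.level} does not match n={n}")
    if len(sequence) < n:
        raise ValueError(f"sequence of length {len(sequence)} is shorter than n={n}")
    windows = [(j, sequence[j : j + n]) for j in range(len(sequence) - n + 1)]
    found = [(j, g) for j, g in windows if g in table]
    coverage = len(found) / len(windows)
    if not found:
        logger.warning("protein %r: no n-gram found in embedding table", protein_id)
        return PooledProtein(protein_id, np.zeros(table.dim), [], 0.0)
    vectors = np.stack([table[g] for _, g in found])
    pooled, alpha = attention_pool(vectors)
    attention = [(j, g, float(a)) for (j, g), a in zip(found, alpha)]
    return PooledProtein(protein_id, pooled, attention, coverage)


def save_protein_embeddings(
    path: str,
    embeddings: dict[str, np.ndarray],
    coverage: dict[str, float] | None = None,
) -> None:
    """Write a header TSV of protein_id, coverage and the embedding vector."""
    dim = len(next(iter(embeddings.values())))
    with open(path, "w") as fh:
        fh.write("protein_id\tcoverage\t" + "\t".join(f"v{i}" for i in range(dim)) + "\n")
        for pid, vec in embeddings.items():
            cov = 1.0 if coverage is None else coverage.get(pid, 1.0)
            fh.write(f"{pid}\t{cov:.6g}\t" + "\t".join(f"{x:.10g}" for x in vec) + "\n")


def load_protein_embeddings(path: str) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Inverse of :func:`save_protein_embeddings`: (vectors, coverages)."""
    vectors: dict[str, np.ndarray] = {}
    coverages: dict[str, float] = {}
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            vectors[parts[0]] = np.array([float(x) for x in parts[2:]])
            coverages[parts[0]] = float(parts[1])
    return vectors, coverages


def save_attention(path: str, pooled: list[PooledProtein]) -> None:
    """Per-protein attention dump: protein_id, window position, n-gram, weight."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tngram\tweight\n")
        for p in pooled:
            for pos, gram, w in p.attention:
                fh.write(f"{p.protein_id}\t{pos}\t{gram}\t{w:.10g}\n")


@dataclass
class PCAReducer:
    """Fitted centering + projection, reusable on held-out vectors."""

    mean: np.ndarray
    components: np.ndarray  # (target_dim, d); zero rows pad missing rank

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) @ self.components.T


def pca_reduce(matrix: np.ndarray, target_dim: int = PCA_TARGET_DIM) -> tuple[np.ndarray, PCAReducer]:
    """Center and project protein vectors onto the top principal axes.

    If the input dimension is already <= ``target_dim`` the data is only
    centered (shape preserved).  When the achievable rank is below
    ``target_dim``, the missing components are zero rows (with a logged
    rank warning), keeping the output dimension fixed.
    """
    x = np.asarray(matrix, dtype=float)
    n, d = x.shape
    if d <= target_dim:
        mean = x.mean(axis=0)
        reducer = PCAReducer(mean=mean, components=np.eye(d))
        return x - mean, reducer
    k = min(target_dim, n, d)
    pca = PCA(n_components=k, svd_solver="full")
    reduced = pca.fit_transform(x)
    components = pca.components_
    if k < target_dim:
        logger.warning("PCA rank %d below target dimension %d; zero-padding", k, target_dim)
        components = np.vstack([components, np.zeros((target_dim - k, d))])
        reduced = np.hstack([reduced, np.zeros((n, target_dim - k))])
    return reduced, PCAReducer(mean=pca.mean_, components=components)
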