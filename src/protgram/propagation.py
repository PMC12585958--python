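"""Propagation matrices for the directed graph convolution.

A raw weighted directed adjacency is turned into three matrices used by
every layer:

* ``a_out`` — from the row-normalized adjacency itself,
* ``a_in``  — from the row-normalized transpose,
* ``a_undir`` — the standard symmetrically normalized undirected adjacency.

For the two directed branches the row-normalized matrix M is split into its
symmetric part S = (M + Mᵀ)/2 and skew-symmetric part K = (M − Mᵀ)/2, and the
propagation matrix is the element-wise magnitude sqrt(S∘S + K∘K + ε) plus the
identity for self-loops.  The magnitude map makes the non-Hermitian directed
adjacency symmetric (hence spectrally well behaved) while retaining both the
reciprocal and the directional component of every transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Numerical-stability constant inside the element-wise magnitude.
DEFAULT_EPSILON: float = 1e-9


@dataclass
class PropagationSet:
    """The three per-graph propagation matrices consumed by every layer."""

    a_in: np.ndarray
    a_out: np.ndarray
    a_undir: np.ndarray
    epsilon: float = DEFAULT_EPSILON

    @property
    def n_nodes(self) -> int:
        return self.a_in.shape[0]


def row_normalize(a_raw: np.ndarray) -> np.ndarray:
    """Divide each non-zero row by its sum (weighted out-strength).

    Zero rows pass through unchanged; negative entries are a domain error.
    """
    a_raw = np.asarray(a_raw, dtype=float)
    if (a_raw < 0).any():
        raise ValueError("adjacency entries must be non-negative")
    sums = a_raw.sum(axis=1)
    out = np.zeros_like(a_raw)
    nz = sums > 0
    out[nz] = a_raw[nz] / sums[nz, None]
    return out


def sk_decompose(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a square matrix into symmetric and skew-symmetric components.

    Returns (S, K) with S = (M + Mᵀ)/2, K = (M − Mᵀ)/2; S + K == M exactly.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    s = (m + m.T) / 2.0
    k = (m - m.T) / 2.0
    return s, k


def magnitude_propagation(s: np.ndarray, k: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Element-wise magnitude sqrt(S∘S + K∘K + ε) + I.

    Symmetric by construction since S∘S and K∘K are both symmetric.
    """
    if s.shape != k.shape:
        raise ValueError("S and K must have the same shape")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return np.sqrt(s * s + k * k + epsilon) + np.eye(s.shape[0])


def undirected_normalized(a_raw: np.ndarray) -> np.ndarray:
    """Symmetrically normalized undirected adjacency D̃^{-1/2} (W+I) D̃^{-1/2}.

    W is the weighted symmetrization A_raw + A_rawᵀ; D̃ is the diagonal of
    row sums of W + I.
    """
    a_raw = np.asarray(a_raw, dtype=float)
    if (a_raw < 0).any():
        raise ValueError("adjacency entries must be non-negative")
    w = a_raw + a_raw.T + np.eye(a_raw.shape[0])
    d = w.sum(axis=1)
    d_inv_sqrt = np.zeros_like(d)
    nz = d > 0
    d_inv_sqrt[nz] = 1.0 / np.sqrt(d[nz])
    return w * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _directed_pipeline(a_raw: np.ndarray, epsilon: float) -> np.ndarray:
    s, k = sk_decompose(row_normalize(a_raw))
    return magnitude_propagation(s, k, epsilon)


def build_propagation_set(a_raw: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> PropagationSet:
    """All three propagation matrices from one raw count adjacency.

    The out branch runs the pipeline on A_raw, the in branch on A_rawᵀ; for a
    symmetric adjacency the two coincide exactly.
    """
    a_raw = np.asarray(a_raw, dtype=float)
    if a_raw.ndim != 2 or a_raw.shape[0] != a_raw.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a_raw.shape}")
    return PropagationSet(
        a_in=_directed_pipeline(a_raw.T, epsilon),
        a_out=_directed_pipeline(a_raw, epsilon),
        a_undir=undirected_normalized(a_raw),
        epsilon=epsilon,
    )
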