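"""Hierarchy of global directed, weighted n-gram transition graphs.

A level-n graph G_n has one node per unique n-gram observed in the corpus
token stream and a directed edge (u, v) whenever v immediately follows u
under a one-character window shift; the edge weight is the total count of
that transition across the whole corpus.  The level-1 graph is the empirical
first-order Markov chain over residues (plus the protein-boundary separator
token); row-normalizing its weights gives transition probabilities, and a
protein sequence is a path whose probability is the product of the step
probabilities along it.

Separator convention: the separator is an ordinary token at level 1 (so the
level-1 graph marks protein boundaries), but n-grams containing it are
excluded for n >= 2 and windows spanning a boundary contribute no edges —
higher-order n-grams crossing protein boundaries carry no biological
meaning.  Under this convention the nodes of G_{n+1} are exactly the lifted
edges of G_n (see :func:`lift_level`).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import CleanCorpus


class EmptyGraphError(ValueError):
    """Raised when no n-gram window fits in any sequence."""


class VocabularyError(KeyError):
    """Raised when a symbol or n-gram is missing from a graph vocabulary."""


@dataclass
class NGramGraph:
    """Directed weighted graph of n-gram transitions.

    ``vocab`` is ordered by first occurrence in the token stream, giving a
    deterministic, corpus-stable node indexing.  ``edges`` maps index pairs
    ``(u, v)`` to strictly positive integer transition counts.
    """

    level: int
    vocab: list[str]
    edges: dict[tuple[int, int], int]
    separator: str = "|"
    corpus_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.vocab)}

    @property
    def n_nodes(self) -> int:
        return len(self.vocab)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, u: str, v: str) -> int:
        """Transition count from n-gram ``u`` to ``v`` (0 if absent)."""
        try:
            return self.edges.get((self.index[u], self.index[v]), 0)
        except KeyError as exc:
            raise VocabularyError(f"n-gram not in vocabulary: {exc.args[0]!r}") from exc

    def adjacency(self) -> np.ndarray:
        """Dense raw count adjacency A_raw with (A_raw)[u, v] = w_uv."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=float)
        for (u, v), w in self.edges.items():
            a[u, v] = w
        return a

    def total_weight(self) -> int:
        return sum(self.edges.values())


@dataclass
class TransitionMatrix:
    """Row-stochastic empirical transition matrix over a graph's vocab order."""

    matrix: np.ndarray
    vocab: list[str]
    level: int
    zero_rows: set[int]

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.vocab)}

    def restricted(self, symbols: str) -> np.ndarray:
        """Sub-chain over ``symbols``, rows renormalized.

        Conditions each transition on the successor being one of ``symbols``
        — e.g. to compare the level-1 empirical chain with a generating
        residue chain, excluding the mass spent on boundary separators.
        Rows are returned in the order of ``symbols``.
        """
        idx = [self.index[s] for s in symbols]
        sub = self.matrix[np.ix_(idx, idx)]
        sums = sub.sum(axis=1, keepdims=True)
        return np.divide(sub, sums, out=np.zeros_like(sub), where=sums > 0)


def _iter_segments(corpus: CleanCorpus, n: int):
    """Separator-free segments to scan for n >= 2 (individual sequences)."""
    for seq in corpus.sequences:
        yield seq


def build_ngram_graph(corpus: CleanCorpus, n: int) -> NGramGraph:
    """Count n-gram nodes and one-shift transition edges over the corpus.

    At ``n == 1`` the token stream (sequences joined by the separator) is
    scanned directly, so the separator is a node and boundary transitions are
    edges.  For ``n >= 2`` each sequence is scanned on its own: no
    separator-containing n-grams, no boundary-spanning edges.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(corpus) == 0:
        raise EmptyGraphError("corpus is empty")

    vocab: list[str] = []
    index: dict[str, int] = {}
    edges: dict[tuple[int, int], int] = {}

    def node(g: str) -> int:
        i = index.get(g)
        if i is None:
            i = len(vocab)
            index[g] = i
            vocab.append(g)
        return i

    segments = [corpus.token_stream()] if n == 1 else list(_iter_segments(corpus, n))
    for seg in segments:
        if len(seg) < n:
            continue
        prev = node(seg[:n])
        for j in range(1, len(seg) - n + 1):
            cur = node(seg[j : j + n])
            key = (prev, cur)
            edges[key] = edges.get(key, 0) + 1
            prev = cur
    if not vocab:
        raise EmptyGraphError(f"no {n}-gram fits in any sequence of the corpus")

    meta = {
        "source_path": corpus.source_path,
        "n_sequences": len(corpus),
        "corpus_hash": hashlib.sha256(corpus.token_stream().encode()).hexdigest()[:16],
    }
    return NGramGraph(level=n, vocab=vocab, edges=edges, separator=corpus.separator, corpus_meta=meta)


def transition_probabilities(graph: NGramGraph) -> TransitionMatrix:
    """Normalize each node's outgoing counts by its out-strength.

    Nodes with no outgoing edges keep an all-zero row and are reported in
    ``zero_rows``.
    """
    a = graph.adjacency()
    row_sums = a.sum(axis=1)
    zero_rows = {int(i) for i in np.flatnonzero(row_sums == 0)}
    p = np.zeros_like(a)
    nz = row_sums > 0
    p[nz] = a[nz] / row_sums[nz, None]
    return TransitionMatrix(matrix=p, vocab=list(graph.vocab), level=graph.level, zero_rows=zero_rows)


def sequence_log_probability(tm: TransitionMatrix, sequence: str) -> float:
    """Natural-log probability of a residue sequence under the level-1 chain.

    Sums log step probabilities over the L-1 adjacent pairs; returns ``-inf``
    if any step has probability zero.  Raises :class:`VocabularyError` for
    symbols outside the chain's vocabulary.
    """
    if tm.level != 1:
        raise ValueError("sequence probability requires a level-1 transition matrix")
    try:
        idx = [tm.index[c] for c in sequence]
    except KeyError as exc:
        raise VocabularyError(f"symbol not in vocabulary: {exc.args[0]!r}") from exc
    logp = 0.0
    for a, b in zip(idx[:-1], idx[1:]):
        p = tm.matrix[a, b]
        if p == 0.0:
            return float("-inf")
        logp += float(np.log(p))
    return logp


def lift_level(graph_n: NGramGraph) -> tuple[list[str], dict[str, tuple[str, str]]]:
    """Enumerate level-(n+1) nodes from the edges of G_n.

    Each observed edge (u, v) lifts to the (n+1)-gram ``u + v[-1]`` whose
    constituent parents are (u, v) — prefix and suffix.  Lifted grams
    containing the separator are dropped, matching the vocabulary rule for
    n >= 2, so the returned node list equals the vocabulary of the
    corpus-built G_{n+1} as a set.
    """
    sep = graph_n.separator
    nodes: list[str] = []
    parents: dict[str, tuple[str, str]] = {}
    for (ui, vi) in graph_n.edges:
        u, v = graph_n.vocab[ui], graph_n.vocab[vi]
        gram = u + v[-1]
        if sep in gram or gram in parents:
            continue
        parents[gram] = (u, v)
        nodes.append(gram)
    return nodes, parents


# ---------------------------------------------------------------------------
# Serialization: vocab file + weighted edge list + JSON metadata
# ---------------------------------------------------------------------------

def save_graph(graph: NGramGraph, out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "nodes.txt"), "w") as fh:
        fh.write("\n".join(graph.vocab) + "\n")
    with open(os.path.join(out_dir, "edges.tsv"), "w") as fh:
        for (u, v), w in sorted(graph.edges.items()):
            fh.write(f"{u}\t{v}\t{w}\n")
    meta = {"level": graph.level, "separator": graph.separator, **graph.corpus_meta}
    with open(os.path.join(out_dir, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_graph(out_dir: str | os.PathLike) -> NGramGraph:
    with open(os.path.join(out_dir, "nodes.txt")) as fh:
        vocab = [line.rstrip("\n") for line in fh if line.strip()]
    edges: dict[tuple[int, int], int] = {}
    with open(os.path.join(out_dir, "edges.tsv")) as fh:
        for line in fh:
            u, v, w = line.split("\t")
            edges[(int(u), int(v))] = int(w)
    with open(os.path.join(out_dir, "meta.json")) as fh:
        meta = json.load(fh)
    level = meta.pop("level")
    separator = meta.pop("separator")
    return NGramGraph(level=level, vocab=vocab, edges=edges, separator=separator, corpus_meta=meta)
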