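"""Self-supervised training of the directed GCN over the n-gram hierarchy.

Labels come from the graph itself: below the top level every node is
labeled with its most frequent successor (next-node prediction), which
forces the embeddings to encode the sequential grammar of the corpus; the
top level is labeled by Louvain communities of the symmetrized weighted
graph, an analogue of a wider context window.

Training is hierarchical: level-1 features are the identity matrix, and
each higher level initializes a node's features by attention-pooling the
learned embeddings of its two constituent lower-level n-grams (prefix and
suffix).  Large levels (n >= 3 by default) are trained on community-derived
subgraph mini-batches in the style of cluster-partitioned GCN training;
partitioning is an efficiency device, the objective is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .corpus_io import CleanCorpus
from .directgcn import Adam, DirectGCNModel
from .pooling import EmbeddingTable, attention_pool
from .propagation import build_propagation_set
from .protgram import NGramGraph, VocabularyError, build_ngram_graph, lift_level

logger = logging.getLogger("protgram")


class LabelingError(ValueError):
    """Raised when a label task cannot be defined on the graph."""


class DivergenceError(FloatingPointError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class NodeLabelSet:
    """Per-node class indices with a participation mask."""

    labels: np.ndarray  # (N,) int; arbitrary where mask is False
    mask: np.ndarray    # (N,) bool
    task: str           # "next_node" | "community"
    n_classes: int


@dataclass
class LevelTrainConfig:
    """Optimization settings for one n-gram level."""

    epochs: int = 300
    learning_rate: float = 0.01
    hidden_dims: tuple[int, ...] = (64, 64)
    gating_mode: str = "vector"
    dropout: float = 0.0
    leaky_slope: float = 0.01
    seed: int = 0
    partition_threshold_level: int = 3
    partition_batch_nodes: int = 512

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def next_node_labels(graph: NGramGraph) -> NodeLabelSet:
    """Label each node with its highest-weight successor.

    Ties break toward the smallest vocabulary index; nodes without outgoing
    edges are excluded through the mask.  Classes are the successor node
    indices (contiguous over the full vocabulary).
    """
    n = graph.n_nodes
    best_w = np.zeros(n, dtype=int)
    best_v = np.full(n, -1, dtype=int)
    for (u, v), w in graph.edges.items():
        if w > best_w[u] or (w == best_w[u] and best_v[u] != -1 and v < best_v[u]):
            best_w[u] = w
            best_v[u] = v
    mask = best_v >= 0
    labels = np.where(mask, best_v, 0)
    return NodeLabelSet(labels=labels, mask=mask, task="next_node", n_classes=n)


def _symmetrized_nx(graph: NGramGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    for (u, v), w in graph.edges.items():
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=float(w))
    return g


def community_labels(graph: NGramGraph, resolution: float = 1.0, seed: int = 0) -> NodeLabelSet:
    """Louvain communities of the symmetrized weighted graph as labels.

    Every node is labeled; community ids are re-indexed contiguously, sorted
    by decreasing size (ties by smallest member index) for determinism.
    """
    if graph.n_edges == 0:
        raise LabelingError("community labels require at least one edge")
    g = _symmetrized_nx(graph)
    communities = nx.algorithms.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.zeros(graph.n_nodes, dtype=int)
    for cid, members in enumerate(communities):
        for u in members:
            labels[u] = cid
    return NodeLabelSet(labels=labels, mask=np.ones(graph.n_nodes, dtype=bool),
                        task="community", n_classes=len(communities))


def hierarchical_init(prev_table: EmbeddingTable, graph_n: NGramGraph) -> np.ndarray:
    """Initial features for level n by pooling each node's two parents.

    A level-n node "abc" decomposes into prefix "ab" and suffix "bc"; its H0
    row is the mean-context attention pooling of those two embeddings from
    the previous level's table.
    """
    h0 = np.zeros((graph_n.n_nodes, prev_table.dim))
    for i, gram in enumerate(graph_n.vocab):
        prefix, suffix = gram[:-1], gram[1:]
        for parent in (prefix, suffix):
            if parent not in prev_table:
                raise VocabularyError(
                    f"missing parent embedding {parent!r} for n-gram {gram!r}"
                )
        pooled, _ = attention_pool(np.stack([prev_table[prefix], prev_table[suffix]]))
        h0[i] = pooled
    return h0


def partition_nodes(graph: NGramGraph, target_batch_nodes: int, seed: int = 0) -> list[np.ndarray]:
    """Community-derived mini-batches: Louvain parts merged greedily.

    Communities (largest first) are packed into batches of at most
    ``target_batch_nodes`` nodes; a community larger than the target forms
    its own batch.
    """
    g = _symmetrized_nx(graph)
    communities = nx.algorithms.community.louvain_communities(g, weight="weight", seed=seed)
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    batches: list[list[int]] = []
    for com in communities:
        members = sorted(com)
        if batches and len(batches[-1]) + len(members) <= target_batch_nodes:
            batches[-1].extend(members)
        else:
            batches.append(list(members))
    return [np.array(sorted(b), dtype=int) for b in batches]


def _induced_adjacency(graph: NGramGraph, idx: np.ndarray) -> np.ndarray:
    pos = {int(u): i for i, u in enumerate(idx)}
    a = np.zeros((idx.size, idx.size))
    for (u, v), w in graph.edges.items():
        if u in pos and v in pos:
            a[pos[u], pos[v]] = w
    return a


def train_level(
    graph: NGramGraph,
    labels: NodeLabelSet,
    h0: np.ndarray,
    config: LevelTrainConfig,
) -> tuple[EmbeddingTable, list[dict]]:
    """Train one level and extract its L2-normalized embedding table.

    Adam minimizes the masked mean negative log-likelihood of the decoder
    output.  For levels at or above ``partition_threshold_level`` the graph
    is split into community mini-batches and each epoch sweeps the batches;
    below the threshold every epoch is one full-graph step.  The returned
    history holds one record per epoch with the (batch-averaged) loss.
    """
    if h0.shape[0] != graph.n_nodes:
        raise ValueError("H0 row count must equal the vocabulary size")
    model = DirectGCNModel.init(
        n_nodes=graph.n_nodes,
        f_in=h0.shape[1],
        hidden_dims=config.hidden_dims,
        n_classes=max(labels.n_classes, 2),
        gating_mode=config.gating_mode,
        dropout=config.dropout,
        leaky_slope=config.leaky_slope,
        seed=config.seed,
    )
    optimizer = Adam(model.trainable(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    a_raw = graph.adjacency()
    partitioned = graph.level >= config.partition_threshold_level and graph.n_nodes > config.partition_batch_nodes
    if partitioned:
        batches = partition_nodes(graph, config.partition_batch_nodes, seed=config.seed)
        batch_data = []
        for idx in batches:
            if not labels.mask[idx].any():
                continue
            propset = build_propagation_set(_induced_adjacency(graph, idx))
            batch_data.append((idx, propset))
        if not batch_data:
            raise LabelingError("no labeled nodes in any partition")
        logger.info("level %d: partitioned training over %d batches", graph.level, len(batch_data))
    else:
        full_propset = build_propagation_set(a_raw)

    history: list[dict] = []
    for epoch in range(config.epochs):
        try:
            if partitioned:
                losses = []
                for idx, propset in batch_data:
                    loss, grads = model.loss_and_grads(
                        h0[idx], propset, labels.labels[idx], labels.mask[idx],
                        training=True, rng=rng, node_idx=idx,
                    )
                    optimizer.step(grads)
                    losses.append(loss)
                epoch_loss = float(np.mean(losses))
            else:
                epoch_loss, grads = model.loss_and_grads(
                    h0, full_propset, labels.labels, labels.mask, training=True, rng=rng,
                )
                optimizer.step(grads)
        except FloatingPointError as exc:
            raise DivergenceError(epoch) from exc
        history.append({"epoch": epoch, "loss": epoch_loss})

    eval_propset = build_propagation_set(a_raw)
    z = model.embeddings(h0, eval_propset)
    table = EmbeddingTable(vocab=list(graph.vocab), vectors=z, level=graph.level)
    logp = model.decode(model.forward(h0, eval_propset))
    pred = logp.argmax(axis=1)
    m = labels.mask
    history[-1]["train_accuracy"] = float((pred[m] == labels.labels[m]).mean())
    return table, history


def train_hierarchy(
    corpus: CleanCorpus,
    n_max: int,
    configs: LevelTrainConfig | list[LevelTrainConfig] | None = None,
    louvain_resolution: float = 1.0,
    return_all_levels: bool = False,
) -> EmbeddingTable | dict[int, EmbeddingTable]:
    """Train levels 1..n_max in order and return the top-level table.

    Level 1 starts from identity features; each higher level starts from
    attention-pooled parent embeddings.  Levels below ``n_max`` train on
    next-node prediction, the top level on Louvain community labels (when
    the top-level graph has edges; otherwise next-node is used).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if configs is None:
        configs = LevelTrainConfig()
    if isinstance(configs, LevelTrainConfig):
        configs = [replace(configs) for _ in range(n_max)]
    if len(configs) != n_max:
        raise ValueError(f"expected {n_max} level configs, got {len(configs)}")

    tables: dict[int, EmbeddingTable] = {}
    prev_table: EmbeddingTable | None = None
    for n in range(1, n_max + 1):
        graph = build_ngram_graph(corpus, n)
        if n == 1:
            h0 = np.eye(graph.n_nodes)
        else:
            h0 = hierarchical_init(prev_table, graph)
        if n == n_max and graph.n_edges > 0:
            labels = community_labels(graph, resolution=louvain_resolution, seed=configs[n - 1].seed)
        else:
            labels = next_node_labels(graph)
        table, history = train_level(graph, labels, h0, configs[n - 1])
        logger.info(
            "level %d: %d nodes, %d edges, task=%s, final loss %.4f",
            n, graph.n_nodes, graph.n_edges, labels.task, history[-1]["loss"],
        )
        tables[n] = table
        prev_table = table
    return tables if return_all_levels else tables[n_max]
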