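"""End-to-end composition: corpus -> hierarchy -> pooled proteins -> CV.

Thin glue over the library modules; each stage is the public function of
its own module, so this file contains no logic of its own beyond wiring.
"""

from __future__ import annotations

import logging

import numpy as np

from .corpus_io import CleanCorpus, PairTable
from .pooling import EmbeddingTable, pca_reduce, protein_embedding
from .ppi_eval import CVSummary, MLPConfig, PPIDataset, cross_validate
from .training import LevelTrainConfig, train_hierarchy

logger = logging.getLogger("protgram")


def embed_proteins(
    corpus: CleanCorpus,
    table: EmbeddingTable,
    pca_dim: int = 64,
) -> dict[str, np.ndarray]:
    """Pool every corpus protein with the table's n-grams, then PCA-reduce."""
    n = table.level
    ids, vectors = [], []
    for pid, seq in zip(corpus.ids, corpus.sequences):
        if len(seq) < n:
            continue
        pooled = protein_embedding(seq, table, n, protein_id=pid)
        ids.append(pid)
        vectors.append(pooled.vector)
    reduced, _ = pca_reduce(np.stack(vectors), target_dim=pca_dim)
    return dict(zip(ids, reduced))


def planted_signal_run(
    corpus: CleanCorpus,
    pairs: PairTable,
    n_max: int = 2,
    level_config: LevelTrainConfig | None = None,
    mlp_config: MLPConfig | None = None,
    k: int = 5,
    seed: int = 0,
    pca_dim: int = 64,
) -> CVSummary:
    """Full pipeline: build/train the hierarchy, pool, PCA, stratified CV."""
    if level_config is None:
        level_config = LevelTrainConfig(seed=seed)
    table = train_hierarchy(corpus, n_max=n_max, configs=level_config)
    embeddings = embed_proteins(corpus, table, pca_dim=pca_dim)
    dataset = PPIDataset.from_table(pairs, embeddings)
    return cross_validate(dataset, mlp_config=mlp_config, k=k, seed=seed)
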