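"""PPI link-prediction evaluation: pair features, classifier, CV, metrics.

A protein pair is represented by the concatenation of the two pooled
protein embeddings (128 features after PCA to 64).  A multilayer perceptron
is trained and scored under stratified k-fold cross-validation, reporting
ROC AUC, F1, precision and recall per fold and as mean ± standard
deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .corpus_io import PairTable

logger = logging.getLogger("protgram")


class StratificationError(ValueError):
    """Raised when cross-validation folds cannot be formed."""


class MetricError(ValueError):
    """Raised when a metric is undefined for the given labels."""


@dataclass
class MLPConfig:
    """Classifier settings for the pair MLP."""

    hidden_layer_sizes: tuple[int, ...] = (128, 64)
    max_iter: int = 300
    early_stopping: bool = True
    validation_fraction: float = 0.1
    alpha: float = 1e-4


@dataclass
class FoldResult:
    fold: int
    auc: float
    f1: float
    precision: float
    recall: float
    threshold: float = 0.5


@dataclass
class CVSummary:
    folds: list[FoldResult]
    mean: dict[str, float]
    std: dict[str, float]


@dataclass
class PPIDataset:
    """Labeled protein pairs joined with per-protein pooled embeddings.

    Pairs whose proteins lack an embedding are dropped at construction with
    a logged count.
    """

    features: np.ndarray  # (n_pairs, 2*d)
    labels: np.ndarray    # (n_pairs,) in {0, 1}
    pair_ids: list[tuple[str, str]]
    n_dropped: int = 0

    @classmethod
    def from_table(cls, table: PairTable, embeddings: dict[str, np.ndarray]) -> "PPIDataset":
        feats, labels, ids = [], [], []
        dropped = 0
        for row in table.pairs.itertuples(index=False):
            va = embeddings.get(row.id_a)
            vb = embeddings.get(row.id_b)
            if va is None or vb is None:
                dropped += 1
                continue
            feats.append(np.concatenate([va, vb]))
            labels.append(int(row.label))
            ids.append((row.id_a, row.id_b))
        if dropped:
            logger.warning("dropped %d pair(s) with missing protein embeddings", dropped)
        if not feats:
            raise ValueError("no pair has embeddings for both proteins")
        return cls(np.stack(feats), np.asarray(labels), ids, dropped)


def pair_features(pair: tuple[str, str], embeddings: dict[str, np.ndarray]) -> np.ndarray:
    """Concatenate the two protein vectors: [v_a ; v_b]."""
    a, b = pair
    if a not in embeddings:
        raise KeyError(f"no embedding for protein {a!r}")
    if b not in embeddings:
        raise KeyError(f"no embedding for protein {b!r}")
    return np.concatenate([embeddings[a], embeddings[b]])


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float, float, float]:
    """(AUC, F1, precision, recall); AUC uses midrank tie handling.

    Thresholded predictions feed F1/precision/recall; all-equal scores give
    AUC 0.5.  One-class label vectors leave the AUC undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise MetricError("AUC is undefined for single-class labels")
    auc = float(roc_auc_score(labels, scores))
    preds = (scores >= threshold).astype(int)
    return (
        auc,
        float(f1_score(labels, preds, zero_division=0)),
        float(precision_score(labels, preds, zero_division=0)),
        float(recall_score(labels, preds, zero_division=0)),
    )


def cross_validate(
    dataset: PPIDataset,
    mlp_config: MLPConfig | None = None,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVSummary:
    """Stratified k-fold CV of the pair MLP.

    Folds preserve the class ratio to within one sample.  Each fold trains
    a fresh MLP on the remaining k-1 folds and is scored on the held-out
    fold.
    """
    if mlp_config is None:
        mlp_config = MLPConfig()
    classes, counts = np.unique(dataset.labels, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both classes must be present for stratified CV")
    if k > counts.min():
        raise StratificationError(
            f"k={k} exceeds the minority class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[FoldResult] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(dataset.features, dataset.labels)):
        clf = MLPClassifier(
            hidden_layer_sizes=mlp_config.hidden_layer_sizes,
            max_iter=mlp_config.max_iter,
            early_stopping=mlp_config.early_stopping,
            validation_fraction=mlp_config.validation_fraction,
            alpha=mlp_config.alpha,
            random_state=seed + fold,
        )
        clf.fit(dataset.features[train_idx], dataset.labels[train_idx])
        scores = clf.predict_proba(dataset.features[test_idx])[:, 1]
        auc, f1, prec, rec = compute_metrics(scores, dataset.labels[test_idx], threshold)
        folds.append(FoldResult(fold, auc, f1, prec, rec, threshold))
    metrics = ("auc", "f1", "precision", "recall")
    mean = {m: float(np.mean([getattr(f, m) for f in folds])) for m in metrics}
    std = {m: float(np.std([getattr(f, m) for f in folds])) for m in metrics}
    return CVSummary(folds=folds, mean=mean, std=std)
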