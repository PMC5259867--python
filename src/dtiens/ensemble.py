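"""Imbalance-aware ensemble of feature-subspaced decision trees.

The model trains T binary decision trees. Each tree i gets its own view of
the problem:

1. a random feature subspace F_i — floor(2/3 |F|) of the concatenated
   drug+target pair features, drawn uniformly without replacement;
2. the positive pairs projected onto F_i, clustered with K-means++ into (up
   to) K groups and oversampled so every group reaches the size of the
   largest (within-class balancing);
3. a fresh negative set N_i of exactly the same size as the oversampled
   positives, drawn from the unlabeled grid disjointly from all earlier
   learners' draws (between-class balancing with broad majority coverage).

Every per-learner training set is therefore exactly 1:1 in class sizes.
Prediction is the plain arithmetic mean over the T trees of the positive-
class fraction at each tree's reached leaf, giving a score in [0, 1]
suitable for ranking and ROC analysis.

Reproducibility: the master seed spawns one independent substream per
learner index, so results do not depend on execution order; the shared
negative pool is drawn from in learner order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .data import PairFeaturizer
from .imbalance import (NegativePool, cluster_positives, oversample_rows)

SUBSPACE_FRACTION = 2.0 / 3.0
DEFAULT_T = 500
DEFAULT_K = 100

# Fully grown Gini trees, minimum leaf size 1, no per-split feature
# sampling: the only diversity mechanisms are the per-learner subspace,
# oversampling draw and negative set.
DEFAULT_TREE_PARAMS: dict = {
    "criterion": "gini",
    "max_depth": None,
    "min_samples_leaf": 1,
    "max_features": None,
}


def subspace_size(n_features: int, fraction: float = SUBSPACE_FRACTION) -> int:
    """Number of features each learner sees: floor(fraction * |F|)."""
    return int(math.floor(fraction * n_features))


def select_subspace(n_features: int, rng: int | np.random.Generator,
                    fraction: float = SUBSPACE_FRACTION) -> np.ndarray:
    """Uniform random feature subset without replacement, sorted ascending."""
    if n_features < 2:
        raise ValueError("need at least 2 features to subspace")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    size = subspace_size(n_features, fraction)
    if size < 1:
        raise ValueError("subspace fraction leaves no features")
    return np.sort(rng.choice(n_features, size=size, replace=False))


@dataclass
class TreeRecord:
    """One fitted base learner plus its sampling provenance."""

    tree: DecisionTreeClassifier
    subspace: np.ndarray
    cluster_sizes: np.ndarray
    positive_rows: np.ndarray  # rows into the training positive list
    negative_pairs: list[tuple[str, str]]
    replenished: bool

    @property
    def n_positives(self) -> int:
        return len(self.positive_rows)

    @property
    def n_negatives(self) -> int:
        return len(self.negative_pairs)


@dataclass
class EnsembleModel:
    """T subspaced trees with their sampling provenance."""

    records: list[TreeRecord]
    n_features: int
    feature_names: list[str]
    T: int
    K: int
    seed: int
    oversample: bool
    tree_params: dict
    training_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) != self.T:
            raise ValueError("record count does not match T")
        for rec in self.records:
            if rec.subspace.max(initial=-1) >= self.n_features:
                raise ValueError("subspace index outside the feature list")

    @property
    def subspaces(self) -> list[np.ndarray]:
        return [rec.subspace for rec in self.records]

    def tree_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-tree positive-class leaf fractions, shape (T, n_instances)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected full-dimension pair vectors with "
                f"{self.n_features} features, got shape {X.shape}")
        out = np.empty((self.T, len(X)))
        for i, rec in enumerate(self.records):
            proba = rec.tree.predict_proba(X[:, rec.subspace])
            pos_col = int(np.where(rec.tree.classes_ == 1)[0][0])
            out[i] = proba[:, pos_col]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Ensemble score per pair: mean of the T tree outputs, in [0, 1]."""
        return self.tree_scores(X).mean(axis=0)

    def predict_pairs(self, featurizer: PairFeaturizer,
                      pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        return self.predict(featurizer.matrix(pairs))


def train(positive_pairs: Sequence[tuple[str, str]],
          featurizer: PairFeaturizer,
          pool: NegativePool,
          T: int = DEFAULT_T,
          K: int = DEFAULT_K,
          seed: int = 0,
          oversample: bool = True,
          subspace_fraction: float = SUBSPACE_FRACTION,
          tree_params: dict | None = None) -> EnsembleModel:
    """Fit the T-tree imbalance-aware ensemble.

    For each learner: select F_i, project the positives onto it, cluster
    them into (up to) K groups and oversample every group to the largest
    group's size, then draw |N_i| = |P_i| fresh negatives from ``pool``
    (disjoint across learners until the pool is exhausted) and fit a fully
    grown tree on the balanced set. ``oversample=False`` skips the
    within-class balancing (each learner trains on the raw positives),
    which is the ablation used to isolate the small-disjunct benefit.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    positive_pairs = list(positive_pairs)
    if not positive_pairs:
        raise ValueError("need at least one positive pair")
    params = dict(DEFAULT_TREE_PARAMS)
    if tree_params:
        params.update(tree_params)

    P_full = featurizer.matrix(positive_pairs)
    n_features = featurizer.n_features
    children = np.random.SeedSequence(seed).spawn(T)

    records: list[TreeRecord] = []
    for i in range(T):
        rng = np.random.default_rng(children[i])
        kmeans_seed, tree_seed = (
            int(s % (2**31 - 1)) for s in rng.integers(0, 2**31 - 1, size=2))
        F_i = select_subspace(n_features, rng, subspace_fraction)
        P_i = P_full[:, F_i]
        if oversample and K > 1:
            assignment = cluster_positives(P_i, K, seed=kmeans_seed)
            rows = oversample_rows(assignment, rng)
            cluster_sizes = assignment.cluster_sizes
        else:
            rows = np.arange(len(P_i))
            cluster_sizes = np.array([len(P_i)])
        X_pos = P_i[rows]
        neg_pairs = pool.sample(len(rows), rng, label=i)
        replenished = pool.draw_log[-1].replenished
        X_neg = featurizer.matrix(neg_pairs)[:, F_i]
        X = np.vstack([X_pos, X_neg])
        y = np.concatenate([np.ones(len(X_pos), dtype=int),
                            np.zeros(len(X_neg), dtype=int)])
        tree = DecisionTreeClassifier(random_state=tree_seed, **params)
        tree.fit(X, y)
        records.append(TreeRecord(tree=tree, subspace=F_i,
                                  cluster_sizes=cluster_sizes,
                                  positive_rows=rows,
                                  negative_pairs=neg_pairs,
                                  replenished=replenished))
    return EnsembleModel(records=records, n_features=n_features,
                         feature_names=list(featurizer.feature_names),
                         T=T, K=K, seed=seed, oversample=oversample,
                         tree_params=params,
                         training_pairs=positive_pairs)
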