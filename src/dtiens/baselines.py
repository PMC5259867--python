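"""Comparator scorers for the evaluation protocol.

Two formula-level baselines — a nearest-neighbour similarity scorer and a
single decision tree — plus optional generic library classifiers (random
forest, RBF support-vector machine) wired into the same balanced-sampling
protocol. Each baseline trains on the full positive set P and one negative
set of size |P| sampled uniformly from the unlabeled grid; none of them
performs the per-learner subspacing, oversampling or disjoint negative
bagging of the ensemble method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import PairFeaturizer
from .ensemble import DEFAULT_TREE_PARAMS
from .imbalance import NegativePool


@dataclass
class NnModel:
    """Reference positives for the nearest-neighbour similarity scorer."""

    reference_positives: np.ndarray

    def __post_init__(self) -> None:
        self.reference_positives = np.asarray(self.reference_positives,
                                              dtype=np.float64)
        if self.reference_positives.ndim != 2 or not len(
                self.reference_positives):
            raise ValueError("reference positives must be a non-empty matrix")

    @property
    def n_features(self) -> int:
        return self.reference_positives.shape[1]


def fit_nn(reference_positives: np.ndarray) -> NnModel:
    return NnModel(reference_positives)


def nn_score(X: np.ndarray, model: NnModel,
             chunk_size: int = 2048) -> np.ndarray:
    """Similarity of each instance to its nearest known interaction.

    score_a = max_{b in P} exp(-||a - b||^2 / |F|), where |F| is the number
    of features; an instance identical to a reference positive scores
    exactly 1, and every score lies in (0, 1]. Distances are computed in
    chunks so memory stays bounded for large query sets.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"instance dimension {X.shape[1]} != reference dimension "
            f"{model.n_features}")
    out = np.empty(len(X))
    for start in range(0, len(X), chunk_size):
        block = X[start:start + chunk_size]
        d2 = cdist(block, model.reference_positives, metric="sqeuclidean")
        out[start:start + chunk_size] = np.exp(
            -d2.min(axis=1) / model.n_features)
    return out


class _SklearnScorer:
    """Adapter: classifier + the training provenance the protocol records."""

    def __init__(self, clf, featurizer: PairFeaturizer,
                 training_pairs: list[tuple[str, str]],
                 negative_pairs: list[tuple[str, str]],
                 use_decision_function: bool = False):
        self._clf = clf
        self._featurizer = featurizer
        self._use_df = use_decision_function
        self.training_pairs = training_pairs
        self.negative_pairs = negative_pairs

    def score(self, X: np.ndarray) -> np.ndarray:
        if self._use_df:
            return self._clf.decision_function(X)
        pos_col = int(np.where(self._clf.classes_ == 1)[0][0])
        return self._clf.predict_proba(X)[:, pos_col]

    def score_pairs(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        return self.score(self._featurizer.matrix(pairs))


def single_tree_baseline(positive_pairs: Sequence[tuple[str, str]],
                         featurizer: PairFeaturizer,
                         pool: NegativePool,
                         seed: int = 0,
                         tree_params: dict | None = None) -> _SklearnScorer:
    """One decision tree on P plus an equal-size random negative sample.

    The training set is exactly balanced (|negatives| = |P|); scores are the
    positive-class fraction at the reached leaf. Deterministic under a fixed
    seed.
    """
    return _fit_balanced(
        DecisionTreeClassifier, positive_pairs, featurizer, pool, seed,
        {**DEFAULT_TREE_PARAMS, **(tree_params or {})})


def random_forest_baseline(positive_pairs, featurizer, pool, seed=0,
                           **params) -> _SklearnScorer:
    """Generic random-forest comparator on the same balanced 1:1 sample.

    Library defaults, no claim of parity with any externally tuned setup.
    """
    params.setdefault("n_estimators", 100)
    return _fit_balanced(RandomForestClassifier, positive_pairs, featurizer,
                         pool, seed, params)


def svm_baseline(positive_pairs, featurizer, pool, seed=0,
                 **params) -> _SklearnScorer:
    """Generic RBF-SVM comparator; ranks by decision-function margin."""
    return _fit_balanced(SVC, positive_pairs, featurizer, pool, seed, params,
                         use_decision_function=True)


def _fit_balanced(cls, positive_pairs, featurizer, pool, seed, params,
                  use_decision_function=False) -> _SklearnScorer:
    positive_pairs = list(positive_pairs)
    if not positive_pairs:
        raise ValueError("need at least one positive pair")
    rng = np.random.default_rng(seed)
    clf_seed = int(rng.integers(0, 2**31 - 1))
    neg_pairs = pool.sample(len(positive_pairs), rng, label=cls.__name__)
    X = np.vstack([featurizer.matrix(positive_pairs),
                   featurizer.matrix(neg_pairs)])
    y = np.concatenate([np.ones(len(positive_pairs), dtype=int),
                        np.zeros(len(neg_pairs), dtype=int)])
    clf = cls(random_state=clf_seed, **params).fit(X, y)
    return _SklearnScorer(clf, featurizer, positive_pairs, neg_pairs,
                          use_decision_function=use_decision_function)
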