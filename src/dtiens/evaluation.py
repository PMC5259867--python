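"""ROC/AUC scoring, 5-fold cross-validation, and cold-start case studies.

AUC is computed as the Mann–Whitney statistic — the probability that a
random positive outranks a random negative, with ties credited 1/2 — which
is identical to the trapezoidal area under the ROC curve and is insensitive
to the extreme class skew of interaction data.

Cross-validation partitions the *positive* pairs into near-equal folds. For
each fold the evaluated method trains on the remaining positives (drawing
its negatives from the unlabeled grid with every test pair excluded) and is
scored on the held-out positives plus an equal number of freshly drawn
negatives, disjoint from all training negatives.

The cold-start ("new drug" / "new target") protocol removes every pair
involving the held-out entity from both the training positives and the
negative pool, retrains, scores all candidate partners on the opposite
side, and reports the top-k ranking with known-partner annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from . import baselines, ensemble
from .data import EntityFeatureTable, InteractionSet, PairFeaturizer
from .imbalance import NegativePool


@dataclass
class RocResult:
    """Ranked scores + labels with the derived ROC points and AUC."""

    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def roc_points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


@dataclass
class CvResult:
    method: str
    per_fold_auc: list[float]
    mean_auc: float
    sd_auc: float


@dataclass
class CaseStudyResult:
    entity_id: str
    side: str
    ranking: list[tuple[str, float]]  # (partner id, score), descending score
    top_k: list[tuple[str, float]]
    known_partners: frozenset[str]
    hits: list[str]  # top-k partners that are known true partners
    provenance: dict = field(default_factory=dict)


def compute_auc(scores: Sequence[float],
                labels: Sequence[int]) -> RocResult:
    """AUC via the rank (Mann–Whitney) formulation, plus ROC points.

    Equals the mean over all (positive, negative) score pairs of
    1[s_pos > s_neg] + 0.5 * 1[s_pos == s_neg]. Raises if only one class is
    present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks give ties the 1/2 credit
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(scores=scores, labels=labels, fpr=fpr, tpr=tpr,
                     auc=float(auc))


# ---------------------------------------------------------------------------
# Method registry: a uniform fit(train_pairs, featurizer, pool, seed) -> scorer
# surface over the ensemble and the comparators.


class _EnsembleScorer:
    def __init__(self, model: ensemble.EnsembleModel,
                 featurizer: PairFeaturizer):
        self.model = model
        self._featurizer = featurizer
        self.training_pairs = model.training_pairs

    def score(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)

    def score_pairs(self, pairs) -> np.ndarray:
        return self.model.predict_pairs(self._featurizer, pairs)


class _NnScorer:
    def __init__(self, model: baselines.NnModel, featurizer: PairFeaturizer,
                 training_pairs):
        self.model = model
        self._featurizer = featurizer
        self.training_pairs = training_pairs

    def score(self, X: np.ndarray) -> np.ndarray:
        return baselines.nn_score(X, self.model)

    def score_pairs(self, pairs) -> np.ndarray:
        return self.score(self._featurizer.matrix(pairs))


def _fit_proposed(train_pairs, featurizer, pool, seed, **params):
    model = ensemble.train(train_pairs, featurizer, pool, seed=seed, **params)
    return _EnsembleScorer(model, featurizer)


def _fit_nn(train_pairs, featurizer, pool, seed, **params):
    del pool, seed  # similarity to P needs no negatives and no randomness
    return _NnScorer(baselines.fit_nn(featurizer.matrix(train_pairs)),
                     featurizer, list(train_pairs))


METHODS: dict[str, Callable] = {
    "proposed": _fit_proposed,
    "nn": _fit_nn,
    "tree": baselines.single_tree_baseline,
    "rf": baselines.random_forest_baseline,
    "svm": baselines.svm_baseline,
}


def fit_method(name: str, train_pairs, featurizer, pool, seed, **params):
    try:
        fitter = METHODS[name]
    except KeyError:
        raise ValueError(
            f"unknown method {name!r}; choose from {sorted(METHODS)}") from None
    return fitter(train_pairs, featurizer, pool, seed=seed, **params)


# ---------------------------------------------------------------------------
# Cross-validation


def make_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of range(n) into near-equal folds (sizes differ <= 1)."""
    if n < folds:
        raise ValueError(f"cannot split {n} positives into {folds} folds")
    return [np.sort(f) for f in np.array_split(rng.permutation(n), folds)]


def cross_validate(drugs: EntityFeatureTable, targets: EntityFeatureTable,
                   interactions: InteractionSet, method: str = "proposed",
                   folds: int = 5, seed: int = 0,
                   test_negatives: str = "sampled",
                   exhaustion_policy: str = "replenish",
                   **method_params) -> CvResult:
    """K-fold CV over the positive pairs with per-fold AUC.

    ``test_negatives="sampled"`` (default) scores each fold on its held-out
    positives plus an equal number of negatives drawn before training and
    excluded from the training pool; ``"all"`` scores the full residual grid
    (every pair that is neither a positive nor a training negative), which
    is only practical on small grids. Feature tables are expected to be
    preprocessed already.
    """
    if test_negatives not in ("sampled", "all"):
        raise ValueError(f"unknown test-negative mode {test_negatives!r}")
    featurizer = PairFeaturizer(drugs, targets)
    pairs = list(interactions.pairs)
    master = np.random.SeedSequence(seed)
    fold_children = master.spawn(folds)
    fold_idx = make_folds(len(pairs), folds,
                          np.random.default_rng(master.spawn(1)[0]))

    per_fold = []
    for f, test_rows in enumerate(fold_idx):
        rng = np.random.default_rng(fold_children[f])
        method_seed = int(rng.integers(0, 2**31 - 1))
        test_mask = np.zeros(len(pairs), dtype=bool)
        test_mask[test_rows] = True
        test_pos = [pairs[i] for i in test_rows]
        train_pos = [p for p, held in zip(pairs, test_mask) if not held]
        pool = NegativePool(interactions, policy=exhaustion_policy)
        if test_negatives == "sampled":
            test_neg = pool.sample(len(test_pos), rng, label=f"test-fold-{f}")
            pool.exclude(test_neg)  # survives any replenish during training
        scorer = fit_method(method, train_pos, featurizer, pool,
                            seed=method_seed, **method_params)
        if test_negatives == "all":
            test_neg = pool.residual_pairs()
        scores = scorer.score_pairs(test_pos + test_neg)
        labels = np.concatenate([np.ones(len(test_pos), dtype=int),
                                 np.zeros(len(test_neg), dtype=int)])
        per_fold.append(compute_auc(scores, labels).auc)
    return CvResult(method=method, per_fold_auc=per_fold,
                    mean_auc=float(np.mean(per_fold)),
                    sd_auc=float(np.std(per_fold, ddof=1)))


# ---------------------------------------------------------------------------
# Hold-out split & cold-start case study


def holdout_split(interactions: InteractionSet, test_fraction: float,
                  seed: int = 0,
                  groups: dict[tuple[str, str], int] | None = None
                  ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Random (train, test) split of the positive pairs.

    With ``groups`` (e.g. pair -> concept id) the split is stratified so
    every group contributes ~test_fraction of its members, at least one when
    it has two or more.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pairs = list(interactions.pairs)
    if groups is None:
        buckets = {0: list(range(len(pairs)))}
    else:
        buckets = {}
        for i, p in enumerate(pairs):
            buckets.setdefault(groups.get(p, -1), []).append(i)
    test_rows: list[int] = []
    for _, rows in sorted(buckets.items(), key=lambda kv: str(kv[0])):
        n_test = int(round(test_fraction * len(rows)))
        if len(rows) >= 2:
            n_test = min(max(n_test, 1), len(rows) - 1)
        if n_test:
            test_rows.extend(rng.choice(rows, size=n_test, replace=False))
    test_set = set(test_rows)
    train = [p for i, p in enumerate(pairs) if i not in test_set]
    test = [p for i, p in enumerate(pairs) if i in test_set]
    return train, test


def leave_out_entity(entity_id: str, side: str,
                     drugs: EntityFeatureTable, targets: EntityFeatureTable,
                     interactions: InteractionSet, method: str = "proposed",
                     k: int = 20, seed: int = 0,
                     exhaustion_policy: str = "replenish",
                     **method_params) -> CaseStudyResult:
    """Simulate a new drug (or new target) and rank its candidate partners.

    All pairs involving the entity are removed from the training positives
    and excluded from the negative pool, so no learner sees the entity at
    all. After training, every opposite-side entity is scored as a candidate
    partner; ties in the descending-score ranking break by ascending id.
    """
    if side not in ("drug", "target"):
        raise ValueError(f"side must be 'drug' or 'target', got {side!r}")
    table = drugs if side == "drug" else targets
    if entity_id not in table:
        raise KeyError(f"unknown {side} id: {entity_id!r}")
    col = 0 if side == "drug" else 1
    known = frozenset(p[1 - col] for p in interactions.pairs
                      if p[col] == entity_id)
    if not known:
        raise ValueError(f"{entity_id!r} has no known partners to account for")

    train_interactions = interactions.without_entity(entity_id, side)
    candidates = (interactions.target_universe if side == "drug"
                  else interactions.drug_universe)
    entity_pairs = ([(entity_id, c) for c in candidates] if side == "drug"
                    else [(c, entity_id) for c in candidates])
    pool = NegativePool(train_interactions, excluded_pairs=entity_pairs,
                        policy=exhaustion_policy)
    featurizer = PairFeaturizer(drugs, targets)
    scorer = fit_method(method, train_interactions.pairs, featurizer, pool,
                        seed=seed, **method_params)
    scores = scorer.score_pairs(entity_pairs)
    order = sorted(range(len(candidates)),
                   key=lambda i: (-scores[i], candidates[i]))
    ranking = [(candidates[i], float(scores[i])) for i in order]
    top_k = ranking[:k]
    hits = [c for c, _ in top_k if c in known]
    provenance = {
        "training_pairs": set(train_interactions.pairs),
        "negative_draws": pool.draw_log,
    }
    if hasattr(scorer, "model") and hasattr(scorer.model, "records"):
        provenance["model"] = scorer.model
    return CaseStudyResult(entity_id=entity_id, side=side, ranking=ranking,
                           top_k=top_k, known_partners=known, hits=hits,
                           provenance=provenance)


def rare_concept_recall(rare_scores: Sequence[float],
                        negative_scores: Sequence[float]) -> float:
    """Fraction of held-out rare-concept positives above the median negative.

    A threshold-free small-disjunct metric: it asks whether the rare
    subtype's members are ranked in the upper half of the negative score
    distribution.
    """
    rare_scores = np.asarray(rare_scores, dtype=np.float64)
    negative_scores = np.asarray(negative_scores, dtype=np.float64)
    if rare_scores.size == 0 or negative_scores.size == 0:
        raise ValueError("need non-empty rare and negative score sets")
    med = np.median(negative_scores)
    return float(np.mean(rare_scores > med))
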