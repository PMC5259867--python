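import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtiens import synthgen
from dtiens.data import PairFeaturizer
from dtiens.evaluation import (compute_auc, cross_validate, holdout_split,
                               leave_out_entity, make_folds,
                               rare_concept_recall)


def brute_force_auc(scores, labels):
    """Pairwise Mann-Whitney: mean over (pos, neg) pairs of win/tie credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeAuc:
    def test_worked_example(self):
        result = compute_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert result.auc == pytest.approx(0.75, abs=1e-15)

    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.2, 0.1],
                           [1, 1, 0, 0]).auc == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc([0.1, 0.2], [1, 1])

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(5, 200))
            scores = rng.uniform(size=n).round(1)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            fast = compute_auc(scores, labels).auc
            assert fast == pytest.approx(brute_force_auc(scores, labels),
                                         abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = rng.normal(size=n)
        labels = np.concatenate([[0, 1], rng.integers(0, 2, size=n - 2)])
        a = compute_auc(scores, labels).auc
        b = compute_auc(np.exp(3 * scores) + 7, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_roc_points_anchored_and_monotone(self):
        rng = np.random.default_rng(3)
        result = compute_auc(rng.uniform(size=50),
                             rng.integers(0, 2, size=50) | np.arange(50) % 2)
        pts = result.roc_points
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()


class TestFolds:
    def test_ten_positives_five_even_folds(self):
        folds = make_folds(10, 5, np.random.default_rng(0))
        assert sorted(len(f) for f in folds) == [2, 2, 2, 2, 2]

    def test_paper_scale_fold_sizes(self):
        folds = make_folds(12674, 5, np.random.default_rng(1))
        assert sorted(len(f) for f in folds) == [2534, 2535, 2535, 2535, 2535]

    def test_true_partition(self):
        folds = make_folds(103, 5, np.random.default_rng(2))
        union = np.concatenate(folds)
        assert len(union) == 103
        assert len(set(union.tolist())) == 103


@pytest.fixture(scope="module")
def cv_dataset():
    cfg = synthgen.SynthConfig(n_drugs=60, n_targets=60, n_positives=120,
                               n_concepts=2, noise_sd=0.05, seed=3)
    return synthgen.generate(cfg)


class TestCrossValidate:
    def test_proposed_beats_chance_and_is_deterministic(self, cv_dataset):
        drugs, targets, inter, _ = cv_dataset
        kwargs = dict(method="proposed", folds=5, seed=5, T=10, K=3)
        a = cross_validate(drugs, targets, inter, **kwargs)
        b = cross_validate(drugs, targets, inter, **kwargs)
        assert len(a.per_fold_auc) == 5
        assert a.per_fold_auc == b.per_fold_auc
        assert a.mean_auc == pytest.approx(np.mean(a.per_fold_auc))
        assert a.sd_auc == pytest.approx(np.std(a.per_fold_auc, ddof=1))
        assert a.mean_auc > 0.7

    def test_baseline_methods_run(self, cv_dataset):
        drugs, targets, inter, _ = cv_dataset
        for method in ("nn", "tree"):
            result = cross_validate(drugs, targets, inter, method=method,
                                    folds=3, seed=1)
            assert 0.0 <= result.mean_auc <= 1.0

    def test_all_negative_mode(self, cv_dataset):
        drugs, targets, inter, _ = cv_dataset
        result = cross_validate(drugs, targets, inter, method="nn",
                                folds=3, seed=2, test_negatives="all")
        assert 0.0 <= result.mean_auc <= 1.0

    def test_unknown_method_rejected(self, cv_dataset):
        drugs, targets, inter, _ = cv_dataset
        with pytest.raises(ValueError, match="unknown method"):
            cross_validate(drugs, targets, inter, method="oracle")


class TestHoldoutSplit:
    def test_partition_and_fraction(self, cv_dataset):
        _, _, inter, _ = cv_dataset
        train, test = holdout_split(inter, 0.25, seed=0)
        assert len(train) + len(test) == inter.n_pairs
        assert not set(train) & set(test)
        assert len(test) == round(0.25 * inter.n_pairs)

    def test_stratified_split_hits_every_group(self, cv_dataset):
        _, _, inter, truth = cv_dataset
        train, test = holdout_split(inter, 0.25, seed=1,
                                    groups=truth.concept_of_pair)
        test_concepts = {truth.concept_of_pair[p] for p in test}
        assert test_concepts == set(range(len(truth.concept_sizes)))


@pytest.fixture(scope="module")
def case(cv_dataset):
    drugs, targets, inter, truth = cv_dataset
    entity = truth.concept_drugs[0][0]
    result = leave_out_entity(entity, "drug", drugs, targets, inter,
                              method="proposed", k=20, seed=4, T=10, K=3)
    return entity, inter, result


class TestLeaveOutEntity:
    def test_returns_exactly_k(self, case):
        _, _, result = case
        assert len(result.top_k) == 20

    def test_no_leakage_into_training(self, case):
        """The left-out entity's pairs appear in no learner's training set."""
        entity, _, result = case
        training = result.provenance["training_pairs"]
        assert all(d != entity for d, _ in training)
        for record in result.provenance["negative_draws"]:
            assert all(d != entity for d, _ in record.pairs)
        model = result.provenance["model"]
        for rec in model.records:
            assert all(d != entity for d, _ in rec.negative_pairs)

    def test_ranking_sorted_with_deterministic_tiebreak(self, case):
        _, _, result = case
        scores = [s for _, s in result.ranking]
        assert scores == sorted(scores, reverse=True)
        for (p1, s1), (p2, s2) in zip(result.ranking, result.ranking[1:]):
            if s1 == s2:
                assert p1 < p2

    def test_recovers_planted_partners(self, case):
        """Most of the left-out drug's true targets rank inside the top-k."""
        _, _, result = case
        recovered = len(result.hits) / len(result.known_partners)
        assert recovered >= 0.8

    def test_unknown_entity_rejected(self, cv_dataset):
        drugs, targets, inter, _ = cv_dataset
        with pytest.raises(KeyError, match="nonesuch"):
            leave_out_entity("nonesuch", "drug", drugs, targets, inter)


class TestRareRecall:
    def test_counts_fraction_above_median_negative(self):
        neg = [0.1, 0.2, 0.3, 0.4, 0.5]
        rare = [0.35, 0.25, 0.9, 0.31]
        assert rare_concept_recall(rare, neg) == pytest.approx(0.75)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            rare_concept_recall([], [0.1])
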