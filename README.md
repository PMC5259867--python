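# dtiens

Class imbalance-aware ensemble learning for drug–target interaction (DTI)
prediction.

## The problem

Chemogenomic DTI prediction treats every (drug, target) pair as a binary
classification instance: the drug's molecular descriptors and the target's
protein-sequence descriptors are concatenated into one feature vector
`[d_1, …, d_m, t_1, …, t_n]`, and known interactions form the positive class.
Two kinds of imbalance degrade this setup:

- **Between-class imbalance** — the known interactions P are a vanishing
  fraction of the drug × target grid; everything else is an unlabeled pool N
  treated as negative. Training on all of N biases any classifier toward
  "no interaction"; training on one small negative sample throws most of the
  majority-class information away.
- **Within-class imbalance (small disjuncts)** — P itself is a mixture of
  interaction subtypes of very unequal sizes, and rare subtypes attract
  disproportionate error because learners favour the well-represented ones.

## The method

`dtiens` trains an ensemble of `T` binary decision trees. Each tree `i`:

1. draws a random feature subspace `F_i` of size `⌊2|F|/3⌋`;
2. projects the positives onto `F_i`, clusters them with K-means++ into (up
   to) `K` groups, and resamples every cluster up to `maxClusterSize` (the
   size of the largest cluster), so each subtype carries equal weight —
   `P_i` has exactly `K′ × maxClusterSize` instances;
3. draws a fresh negative set `N_i` with `|N_i| = |P_i|`, uniformly without
   replacement from the unlabeled grid and **disjoint from every other
   learner's draw**, so the ensemble as a whole covers far more of the
   majority class while each tree trains on an exactly 1:1 set.

The prediction score of a pair is the arithmetic mean over the `T` trees of
the positive-class fraction at each tree's leaf — a value in [0, 1] suited
to ranking and ROC/AUC analysis. Defaults are `T = 500`, `K = 100`.

The package also ships the evaluation protocol around the model: descriptor
preprocessing (constant-feature removal, mean imputation, min-max scaling to
[0, 1]), a nearest-neighbour baseline
(`score_a = max_{b∈P} exp(−‖a−b‖² / |F|)`), a single balanced decision tree
and generic random-forest/SVM comparators, rank-based (Mann–Whitney) AUC
with k-fold cross-validation over the positive pairs, cold-start
("new drug"/"new target") leave-out case studies, and a synthetic-data
generator with planted, unequally sized interaction concepts for end-to-end
testing without external data.

## Worked example

```python
from dtiens import synthgen, ensemble, evaluation
from dtiens.data import PairFeaturizer
from dtiens.imbalance import NegativePool

# 120 drugs x 120 targets, 400 planted interactions in 2 concepts
drugs, targets, inter, truth = synthgen.generate(synthgen.SynthConfig(seed=1))

train_pos, test_pos = evaluation.holdout_split(inter, 0.2, seed=1)
featurizer = PairFeaturizer(drugs, targets)
pool = NegativePool(inter)
import numpy as np
rng = np.random.default_rng(1)
test_neg = pool.sample(len(test_pos), rng)
pool.exclude(test_neg)

model = ensemble.train(train_pos, featurizer, pool, T=50, K=5, seed=1)
scores = model.predict_pairs(featurizer, test_pos + test_neg)
labels = [1] * len(test_pos) + [0] * len(test_neg)
print(f"held-out AUC: {evaluation.compute_auc(scores, labels).auc:.3f}")
```

This prints

```
held-out AUC: 1.000
```

meaning every held-out true interaction outranks every sampled non-pair —
expected here because the generator's default feature noise (0.05) barely
blurs the planted concept regions. The `examples/` directory walks through
each capability (preprocessing, training/prediction, cross-validated method
comparison, cold-start ranking, and the small-disjunct experiment) as short
narrative scripts; the command-line tool `dtiens` exposes the same stages as
`simulate`, `preprocess`, `train`, `predict`, `cv` and `casestudy`
subcommands.

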