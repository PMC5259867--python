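"""Synthetic drug/target data with planted, unequally sized interaction concepts.

The generator emulates the structure the method targets: two entity feature
tables with bounded numeric descriptors, a sparse positive pair set that is
a mixture of "concepts" (interaction subtypes) of very unequal sizes, and a
vastly larger implicit negative pair set.

Each concept c is an axis-aligned box on a small set of signal features: a
drug-side interval and a target-side interval. Concept member drugs (resp.
targets) have their signal features drawn inside the box; background
entities are drawn outside every box. The positive pairs of concept c are
the *complete* subgrid of its member drugs x member targets, so with zero
feature noise the planted rule "drug and target both inside the same box"
is exactly the positive set — any consistent learner can reach AUC 1, which
bounds implementation bugs. Per-concept positive counts follow the
configured weights exactly via largest-remainder rounding, enabling precise
small-disjunct experiments. Feature noise blurs the boxes; label noise
replaces a fraction of planted positives with random off-concept pairs.

What this does NOT emulate about real descriptor data: correlated
descriptors, heavy-tailed scales, similarity structure between related
compounds, and the possibility that "negatives" are undiscovered true
interactions. Passing tests on this generator demonstrate pipeline
correctness, not chemical realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import EntityFeatureTable, InteractionSet

N_SIGNAL_FEATURES = 2  # per side
BOX_MARGIN = 0.15  # fraction of each concept's slot left as gap on each end


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    n_drugs: int = 120
    n_targets: int = 120
    n_drug_features: int = 20
    n_target_features: int = 30
    n_concepts: int = 2
    concept_weights: Sequence[float] | None = None  # None = equal weights
    n_positives: int = 400
    noise_sd: float = 0.05
    label_noise: float = 0.0
    member_spread: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_targets", "n_drug_features",
                     "n_target_features", "n_concepts", "n_positives"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.concept_weights is None:
            self.concept_weights = [1.0 / self.n_concepts] * self.n_concepts
        self.concept_weights = [float(w) for w in self.concept_weights]
        if len(self.concept_weights) != self.n_concepts:
            raise ValueError("need one weight per concept")
        if any(w <= 0 for w in self.concept_weights):
            raise ValueError("concept weights must be positive")
        if abs(sum(self.concept_weights) - 1.0) > 1e-9:
            raise ValueError("concept weights must sum to 1")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.member_spread < 0:
            raise ValueError("member_spread must be >= 0")
        if self.n_positives > self.n_drugs * self.n_targets:
            raise ValueError("requested positives exceed the grid size")
        if min(self.n_drug_features,
               self.n_target_features) < N_SIGNAL_FEATURES:
            raise ValueError(
                f"need >= {N_SIGNAL_FEATURES} features per side")


@dataclass
class GroundTruth:
    """Planted structure: which concept generated each positive pair."""

    concept_of_pair: dict[tuple[str, str], int]  # -1 = label-noise pair
    concept_sizes: list[int]
    drug_signal_features: list[str]
    target_signal_features: list[str]
    boxes: list[tuple[float, float]]  # per-concept interval on signal dims
    concept_drugs: list[list[str]]
    concept_targets: list[list[str]]


def allocate_by_weights(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder allocation: sizes follow the weights exactly.

    Every share is floor(w*total) plus one unit for the largest fractional
    remainders (ties to the lower index); each concept gets at least 1.
    """
    raw = [w * total for w in weights]
    sizes = [int(math.floor(r)) for r in raw]
    remainder = total - sum(sizes)
    order = sorted(range(len(weights)), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    # guarantee non-empty concepts (steal from the largest)
    for i, s in enumerate(sizes):
        if s == 0:
            j = int(np.argmax(sizes))
            sizes[j] -= 1
            sizes[i] += 1
    return sizes


def _subgrid_shape(count: int) -> tuple[int, int]:
    """Factor count = n_drugs x n_targets with n_drugs the largest divisor
    <= sqrt(count), so the member subgrid is as square as possible."""
    best = 1
    for d in range(1, int(math.isqrt(count)) + 1):
        if count % d == 0:
            best = d
    return best, count // best


def concept_boxes(n_concepts: int) -> list[tuple[float, float]]:
    """Disjoint signal-feature intervals: one slot of width 1/n per concept,
    with BOX_MARGIN of the slot trimmed at each end."""
    w = 1.0 / n_concepts
    return [(c * w + BOX_MARGIN * w, (c + 1) * w - BOX_MARGIN * w)
            for c in range(n_concepts)]


def generate(config: SynthConfig) -> tuple[EntityFeatureTable,
                                           EntityFeatureTable,
                                           InteractionSet, GroundTruth]:
    """Build (drug table, target table, interactions, ground truth).

    Deterministic per seed: the same config yields byte-identical tables and
    pair sets.
    """
    rng = np.random.default_rng(config.seed)
    sizes = allocate_by_weights(config.n_positives, config.concept_weights)
    shapes = [_subgrid_shape(s) for s in sizes]
    need_drugs = sum(nd for nd, _ in shapes)
    need_targets = sum(nt for _, nt in shapes)
    if need_drugs > config.n_drugs:
        raise ValueError(
            f"concepts need {need_drugs} member drugs but only "
            f"{config.n_drugs} drugs requested")
    if need_targets > config.n_targets:
        raise ValueError(
            f"concepts need {need_targets} member targets but only "
            f"{config.n_targets} targets requested")

    boxes = concept_boxes(config.n_concepts)
    sig_d = np.sort(rng.choice(config.n_drug_features, N_SIGNAL_FEATURES,
                               replace=False))
    sig_t = np.sort(rng.choice(config.n_target_features, N_SIGNAL_FEATURES,
                               replace=False))

    drug_ids = [f"D{i:04d}" for i in range(config.n_drugs)]
    target_ids = [f"T{i:04d}" for i in range(config.n_targets)]
    drug_X = rng.uniform(size=(config.n_drugs, config.n_drug_features))
    target_X = rng.uniform(size=(config.n_targets, config.n_target_features))

    # assign member entities per concept from a random permutation
    d_perm = rng.permutation(config.n_drugs)
    t_perm = rng.permutation(config.n_targets)
    concept_drugs: list[list[str]] = []
    concept_targets: list[list[str]] = []
    d_pos = t_pos = 0
    for c, (nd, nt) in enumerate(shapes):
        lo, hi = boxes[c]
        d_rows = d_perm[d_pos:d_pos + nd]
        t_rows = t_perm[t_pos:t_pos + nt]
        d_pos += nd
        t_pos += nt
        # Members of a concept are homogeneous across ALL features — a
        # per-concept prototype plus member_spread jitter — so concepts
        # really are clusters under Euclidean distance; the signal features
        # additionally sit inside the concept's box, which is what makes
        # the interaction rule tree-learnable and (at zero noise) exact.
        d_proto = rng.uniform(size=config.n_drug_features)
        t_proto = rng.uniform(size=config.n_target_features)
        drug_X[d_rows] = np.clip(
            d_proto + rng.normal(0.0, config.member_spread,
                                 size=(nd, config.n_drug_features)),
            0.0, 1.0)
        target_X[t_rows] = np.clip(
            t_proto + rng.normal(0.0, config.member_spread,
                                 size=(nt, config.n_target_features)),
            0.0, 1.0)
        drug_X[np.ix_(d_rows, sig_d)] = rng.uniform(
            lo, hi, size=(nd, N_SIGNAL_FEATURES))
        target_X[np.ix_(t_rows, sig_t)] = rng.uniform(
            lo, hi, size=(nt, N_SIGNAL_FEATURES))
        concept_drugs.append([drug_ids[r] for r in d_rows])
        concept_targets.append([target_ids[r] for r in t_rows])

    # background entities: keep their signal features outside every box
    bg_drugs = d_perm[d_pos:]
    bg_targets = t_perm[t_pos:]
    drug_X[np.ix_(bg_drugs, sig_d)] = _sample_outside_boxes(
        rng, boxes, (len(bg_drugs), N_SIGNAL_FEATURES))
    target_X[np.ix_(bg_targets, sig_t)] = _sample_outside_boxes(
        rng, boxes, (len(bg_targets), N_SIGNAL_FEATURES))

    # positives: the full member subgrid of every concept
    pairs: list[tuple[str, str]] = []
    concept_of_pair: dict[tuple[str, str], int] = {}
    for c in range(config.n_concepts):
        for d in concept_drugs[c]:
            for t in concept_targets[c]:
                pairs.append((d, t))
                concept_of_pair[(d, t)] = c

    # label noise: replace a fraction of positives with random off-plan pairs
    n_flip = int(round(config.label_noise * len(pairs)))
    if n_flip:
        pair_set = set(pairs)
        flip_rows = rng.choice(len(pairs), size=n_flip, replace=False)
        for row in flip_rows:
            old = pairs[row]
            while True:
                d = drug_ids[int(rng.integers(config.n_drugs))]
                t = target_ids[int(rng.integers(config.n_targets))]
                if (d, t) not in pair_set:
                    break
            pair_set.discard(old)
            pair_set.add((d, t))
            del concept_of_pair[old]
            pairs[row] = (d, t)
            concept_of_pair[(d, t)] = -1

    # feature noise, applied after the planted structure, clipped to [0, 1]
    if config.noise_sd > 0:
        drug_X = np.clip(
            drug_X + rng.normal(0.0, config.noise_sd, size=drug_X.shape),
            0.0, 1.0)
        target_X = np.clip(
            target_X + rng.normal(0.0, config.noise_sd, size=target_X.shape),
            0.0, 1.0)

    drugs = EntityFeatureTable(
        drug_ids, [f"df{j:03d}" for j in range(config.n_drug_features)],
        drug_X)
    targets = EntityFeatureTable(
        target_ids, [f"tf{j:03d}" for j in range(config.n_target_features)],
        target_X)
    interactions = InteractionSet(pairs, drug_ids, target_ids)
    truth = GroundTruth(
        concept_of_pair=concept_of_pair, concept_sizes=sizes,
        drug_signal_features=[drugs.feature_names[j] for j in sig_d],
        target_signal_features=[targets.feature_names[j] for j in sig_t],
        boxes=boxes, concept_drugs=concept_drugs,
        concept_targets=concept_targets)
    return drugs, targets, interactions, truth


def _sample_outside_boxes(rng: np.random.Generator,
                          boxes: list[tuple[float, float]],
                          shape: tuple[int, ...]) -> np.ndarray:
    """Uniform samples on [0,1] rejected out of every concept interval."""
    out = rng.uniform(size=shape)
    while True:
        inside = np.zeros(shape, dtype=bool)
        for lo, hi in boxes:
            inside |= (out >= lo) & (out <= hi)
        if not inside.any():
            return out
        out[inside] = rng.uniform(size=int(inside.sum()))


def holdout_member_drugs(truth: GroundTruth, interactions: InteractionSet,
                         fraction: float = 0.25, seed: int = 0
                         ) -> tuple[list[tuple[str, str]],
                                    list[tuple[str, str]], set[str]]:
    """Concept-stratified cold-ish holdout: leave out whole member drugs.

    Per concept, ``fraction`` of the member drugs (at least one) are held
    out and *all* of their positive pairs become test positives; the rest
    train. Because a held-out pair's drug never appears in training, this
    measures generalisation to unseen members of each concept — the regime
    where under-representation of a rare concept actually bites — rather
    than recombination of already-seen entities.

    Returns (train_pairs, test_pairs, held_out_drug_ids).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    held: set[str] = set()
    for members in truth.concept_drugs:
        k = min(max(1, int(round(fraction * len(members)))),
                max(len(members) - 1, 1))
        held |= set(rng.choice(members, size=k, replace=False).tolist())
    test = [p for p in interactions.pairs if p[0] in held]
    train = [p for p in interactions.pairs if p[0] not in held]
    if not test or not train:
        raise ValueError("degenerate member-drug holdout")
    return train, test, held


@dataclass
class PerturbationLog:
    constant_features: list[str]
    constant_values: dict[str, float]
    missing_cells: list[tuple[str, str]]  # (entity id, feature name)


def inject_missing_and_constants(table: EntityFeatureTable,
                                 fraction_missing: float = 0.0,
                                 n_constant: int = 0,
                                 seed: int = 0
                                 ) -> tuple[EntityFeatureTable,
                                            PerturbationLog]:
    """Reproducibly dirty a table to exercise the preprocessing pipeline.

    ``n_constant`` whole feature columns are overwritten with a constant;
    ``fraction_missing`` of the remaining cells become missing (capped so
    every column keeps >= 2 observed values). Returns the perturbed table
    and an exact log of what was done.
    """
    if not 0.0 <= fraction_missing < 1.0:
        raise ValueError("fraction_missing must be in [0, 1)")
    if n_constant < 0 or n_constant > table.n_features:
        raise ValueError("n_constant out of range")
    rng = np.random.default_rng(seed)
    matrix = table.matrix.copy()

    const_cols = np.sort(rng.choice(table.n_features, size=n_constant,
                                    replace=False)) if n_constant else np.array(
                                        [], dtype=int)
    const_values: dict[str, float] = {}
    for j in const_cols:
        value = round(float(rng.uniform()), 3)
        matrix[:, j] = value
        const_values[table.feature_names[j]] = value

    missing_cells: list[tuple[str, str]] = []
    if fraction_missing > 0:
        candidate_cols = [j for j in range(table.n_features)
                          if j not in set(const_cols.tolist())]
        max_per_col = max(table.n_entities - 2, 0)
        cells = [(i, j) for j in candidate_cols
                 for i in range(table.n_entities)]
        n_missing = int(round(fraction_missing * len(cells)))
        if n_missing:
            chosen = rng.choice(len(cells), size=n_missing, replace=False)
            per_col: dict[int, int] = {}
            for k in chosen:
                i, j = cells[int(k)]
                if per_col.get(j, 0) >= max_per_col:
                    continue
                per_col[j] = per_col.get(j, 0) + 1
                matrix[i, j] = np.nan
                missing_cells.append((table.ids[i], table.feature_names[j]))

    perturbed = EntityFeatureTable(list(table.ids), list(table.feature_names),
                                   matrix)
    return perturbed, PerturbationLog(
        constant_features=[table.feature_names[j] for j in const_cols],
        constant_values=const_values, missing_cells=missing_cells)
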