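"""Samplers addressing the two class-imbalance problems in interaction data.

Within-class imbalance: the known-interaction (positive) class is a mixture
of interaction subtypes of very unequal sizes; rare subtypes ("small
disjuncts") attract disproportionate error because learners favour the
well-represented ones. :func:`cluster_positives` partitions the positives
with K-means++ and :func:`oversample_clusters` resamples every cluster up to
the size of the largest, so every subtype carries equal weight in training.

Between-class imbalance: the non-interacting pair majority dwarfs the
positives. :class:`NegativePool` draws a fresh 1:1 negative set for each
base learner, uniformly without replacement from the unlabeled grid, and
excludes previously drawn pairs so different learners see disjoint negative
sets — together the ensemble covers far more of the majority class than a
single balanced sample would, without biasing any individual learner.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .data import InteractionSet

logger = logging.getLogger("dtiens")

KMEANS_MAX_ITER = 100
KMEANS_TOL = 1e-4

EXHAUSTION_POLICIES = ("replenish", "with_replacement", "error")


class PoolExhaustedError(RuntimeError):
    """The grid minus the positives cannot supply the requested draw."""


@dataclass
class ClusterAssignment:
    """K-means result with empty clusters dropped (labels compacted to 0..K'-1)."""

    labels: np.ndarray
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.intp)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(len(self.centroids))):
            raise ValueError("cluster labels must be compact 0..K'-1 with no "
                             "empty cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    @property
    def max_cluster_size(self) -> int:
        return int(self.cluster_sizes.max())


def cluster_positives(X: np.ndarray, K: int,
                      seed: int | np.random.Generator = 0,
                      max_iter: int = KMEANS_MAX_ITER,
                      tol: float = KMEANS_TOL) -> ClusterAssignment:
    """Cluster positive instances into (up to) K homogeneous groups.

    K-means++ seeding followed by Lloyd iterations, Euclidean distance,
    a single initialisation. If K exceeds the number of instances the
    effective K' is the instance count; clusters that end up empty (possible
    when the data contain duplicated points) are dropped rather than
    re-seeded, so K' <= K. Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or len(X) < 1:
        raise ValueError("need a non-empty 2-d matrix of positive instances")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    k_eff = min(K, len(X))
    if k_eff == 1:
        return ClusterAssignment(np.zeros(len(X), dtype=np.intp),
                                 X.mean(axis=0, keepdims=True))
    seed_int = _as_seed_int(seed)
    with warnings.catch_warnings():
        # duplicated points can collapse centroids; we compact below
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=k_eff, init="k-means++", n_init=1,
                    max_iter=max_iter, tol=tol,
                    random_state=seed_int).fit(X)
    labels = km.labels_.astype(np.intp)
    present = np.unique(labels)
    remap = {old: new for new, old in enumerate(present)}
    compact = np.fromiter((remap[l] for l in labels), dtype=np.intp,
                          count=len(labels))
    return ClusterAssignment(compact, km.cluster_centers_[present])


def oversample_rows(assignment: ClusterAssignment,
                    rng: int | np.random.Generator) -> np.ndarray:
    """Row indices realising cluster-balanced oversampling.

    Every cluster keeps all of its original members (in original order) and
    is then topped up to ``maxClusterSize`` — the size of the largest
    cluster — by uniform draws with replacement from its own members. The
    result has exactly K' x maxClusterSize rows, clusters in ascending label
    order. A cluster already at the maximum is copied unchanged, and with a
    single cluster the operation is the identity.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    sizes = assignment.cluster_sizes
    max_size = int(sizes.max())
    out: list[np.ndarray] = []
    for cid in range(assignment.n_clusters):
        members = np.where(assignment.labels == cid)[0]
        out.append(members)
        deficit = max_size - len(members)
        if deficit:
            out.append(rng.choice(members, size=deficit, replace=True))
    return np.concatenate(out)


def oversample_clusters(X: np.ndarray, assignment: ClusterAssignment,
                        rng: int | np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Apply cluster-balanced oversampling to the instance matrix.

    Returns ``(enlarged_matrix, row_indices)`` where ``row_indices`` maps
    each output row back to its source row in ``X`` (useful for provenance).
    """
    X = np.asarray(X)
    if len(X) != len(assignment.labels):
        raise ValueError("assignment does not match the instance matrix")
    rows = oversample_rows(assignment, rng)
    return X[rows], rows


@dataclass
class DrawRecord:
    """Log entry for one negative draw: who drew what, and whether the
    disjointness budget had to be reset first."""

    label: object
    pairs: list[tuple[str, str]]
    replenished: bool
    codes: np.ndarray = field(repr=False, default=None)


class NegativePool:
    """Implicit negative pool N = (drug x target grid) minus the positives.

    The grid is indexed as ``code = drug_index * n_targets + target_index``;
    only the positive/excluded codes and the consumed-draw log are ever held
    in memory, so sampling does not require O(grid) storage. Draws are
    uniform without replacement from the remaining pool, and pairs drawn for
    one learner are excluded from later draws (``replenish``/``error``
    policies) so per-learner negative sets are disjoint.

    Exhaustion policy when a draw exceeds the remaining pool:

    - ``replenish`` (default): clear the consumed log, warn, and complete
      the draw — disjointness across learners no longer holds from then on,
      but no learner ever trains on a positive pair.
    - ``with_replacement``: never track consumption; draws are independent
      across learners (each still without replacement internally).
    - ``error``: raise :class:`PoolExhaustedError`.
    """

    def __init__(self, interactions: InteractionSet,
                 excluded_pairs: Iterable[tuple[str, str]] = (),
                 policy: str = "replenish"):
        if policy not in EXHAUSTION_POLICIES:
            raise ValueError(f"unknown exhaustion policy {policy!r}")
        self.policy = policy
        self._drugs = list(interactions.drug_universe)
        self._targets = list(interactions.target_universe)
        self._d_index = {d: i for i, d in enumerate(self._drugs)}
        self._t_index = {t: i for i, t in enumerate(self._targets)}
        self._n_targets = len(self._targets)
        self.grid_size = len(self._drugs) * len(self._targets)
        self._positive_codes = frozenset(
            self._encode(d, t) for d, t in interactions.pairs)
        self._excluded: set[int] = set(self._positive_codes)
        for d, t in excluded_pairs:
            self._excluded.add(self._encode(d, t))
        self._consumed: set[int] = set()
        self.draw_log: list[DrawRecord] = []
        self.replenish_count = 0

    # -- indexing helpers ---------------------------------------------------

    def _encode(self, drug_id: str, target_id: str) -> int:
        try:
            return (self._d_index[drug_id] * self._n_targets
                    + self._t_index[target_id])
        except KeyError as exc:
            raise KeyError(f"pair ({drug_id!r}, {target_id!r}) is outside the "
                           "grid") from exc

    def _decode(self, code: int) -> tuple[str, str]:
        return (self._drugs[code // self._n_targets],
                self._targets[code % self._n_targets])

    # -- public surface -----------------------------------------------------

    @property
    def pool_size(self) -> int:
        """Size of grid \\ (P and extra exclusions), ignoring consumption."""
        return self.grid_size - len(self._excluded)

    @property
    def remaining(self) -> int:
        return self.pool_size - len(self._consumed)

    def exclude(self, pairs: Iterable[tuple[str, str]]) -> None:
        """Permanently remove pairs from the pool (e.g. held-out test pairs)."""
        for d, t in pairs:
            code = self._encode(d, t)
            self._excluded.add(code)
            self._consumed.discard(code)

    def residual_pairs(self) -> list[tuple[str, str]]:
        """Materialise grid \\ excluded \\ consumed (small grids only)."""
        return [self._decode(c) for c in range(self.grid_size)
                if c not in self._excluded and c not in self._consumed]

    def sample(self, size: int, rng: int | np.random.Generator,
               label: object = None) -> list[tuple[str, str]]:
        """Draw ``size`` distinct negative pairs uniformly from the pool."""
        if size < 1:
            raise ValueError(f"draw size must be >= 1, got {size}")
        if self.pool_size < size:
            raise PoolExhaustedError(
                f"grid minus positives holds {self.pool_size} pairs; "
                f"cannot draw {size} even after replenishing")
        rng = np.random.default_rng(rng) if not isinstance(
            rng, np.random.Generator) else rng
        replenished = False
        if self.policy != "with_replacement" and self.remaining < size:
            if self.policy == "error":
                raise PoolExhaustedError(
                    f"{self.remaining} pairs remain but {size} requested")
            self._consumed.clear()
            self.replenish_count += 1
            replenished = True
            logger.warning(
                "negative pool exhausted; replenished consumed log "
                "(draw label=%r, size=%d) — per-learner disjointness no "
                "longer holds", label, size)
        chosen: list[int] = []
        chosen_set: set[int] = set()
        while len(chosen) < size:
            batch = rng.integers(0, self.grid_size,
                                 size=max(64, 2 * (size - len(chosen))))
            for code in batch:
                code = int(code)
                if (code in self._excluded or code in self._consumed
                        or code in chosen_set):
                    continue
                chosen_set.add(code)
                chosen.append(code)
                if len(chosen) == size:
                    break
        if self.policy != "with_replacement":
            self._consumed.update(chosen_set)
        pairs = [self._decode(c) for c in chosen]
        self.draw_log.append(DrawRecord(label=label, pairs=pairs,
                                        replenished=replenished,
                                        codes=np.array(chosen)))
        return pairs


def _as_seed_int(seed: int | np.random.Generator) -> int:
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(0, 2**31 - 1))
    return int(seed) % (2**31 - 1)
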