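"""Readers, writers and pair-instance construction.

The on-disk dialect is tab-separated UTF-8 text with a mandatory header row.
Feature tables carry the entity id in the first column and one named numeric
descriptor per remaining column; ``NA`` or an empty cell marks a missing
value. Interaction lists are two-column tables of (drug_id, target_id).
Lines starting with ``#`` are comments (every file the command-line tool
writes embeds its configuration that way) and are skipped on read.

Entity ids are opaque, case-sensitive strings: DrugBank and UniProt
accessions are case-sensitive in the wild, so no folding is applied.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd

MISSING_MARKERS = ("", "NA")
MODEL_FORMAT_VERSION = "dtiens-model-1"


class DataFormatError(ValueError):
    """Raised when an input file violates the expected dialect or invariants."""


@dataclass(eq=False)
class EntityFeatureTable:
    """Id-indexed matrix of numeric descriptors for drugs or for targets.

    ``matrix`` is float64 with ``NaN`` as the in-memory missing marker.
    Row order follows ``ids``; column order follows ``feature_names``.
    """

    ids: list[str]
    feature_names: list[str]
    matrix: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise DataFormatError("feature matrix must be 2-dimensional")
        if self.matrix.shape != (len(self.ids), len(self.feature_names)):
            raise DataFormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.ids)} ids x {len(self.feature_names)} features"
            )
        dup = _first_duplicate(self.ids)
        if dup is not None:
            raise DataFormatError(f"duplicate entity id: {dup!r}")
        dup = _first_duplicate(self.feature_names)
        if dup is not None:
            raise DataFormatError(f"duplicate feature name: {dup!r}")
        if np.isinf(self.matrix).any():
            raise DataFormatError("feature matrix contains non-finite values")
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n_entities(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.matrix).sum())

    def row(self, entity_id: str) -> np.ndarray:
        try:
            return self.matrix[self._index[entity_id]]
        except KeyError:
            raise KeyError(f"unknown entity id: {entity_id!r}") from None

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index

    def index_of(self, entity_id: str) -> int:
        return self._index[entity_id]

    def subset(self, entity_ids: Sequence[str]) -> "EntityFeatureTable":
        rows = [self._index[i] for i in entity_ids]
        return EntityFeatureTable(list(entity_ids), list(self.feature_names),
                                  self.matrix[rows].copy())

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.matrix, index=pd.Index(self.ids, name="id"),
                             columns=self.feature_names)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EntityFeatureTable":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)),
                   frame.to_numpy(dtype=np.float64))


@dataclass(eq=False)
class InteractionSet:
    """The positive set P of known (drug, target) pairs over a bipartite grid.

    The complement of ``pairs`` over drug_universe x target_universe is the
    implicit negative pool N; it is never materialised (see
    :class:`dtiens.imbalance.NegativePool`).
    """

    pairs: list[tuple[str, str]]
    drug_universe: list[str]
    target_universe: list[str]

    def __post_init__(self) -> None:
        self.pairs = [(str(d), str(t)) for d, t in self.pairs]
        if len(self.pairs) < 1:
            raise DataFormatError("interaction set must contain at least one pair")
        dup = _first_duplicate(self.pairs)
        if dup is not None:
            raise DataFormatError(f"duplicate interaction pair: {dup!r}")
        drugs = set(self.drug_universe)
        targets = set(self.target_universe)
        for d, t in self.pairs:
            if d not in drugs:
                raise DataFormatError(f"pair references unknown drug id: {d!r}")
            if t not in targets:
                raise DataFormatError(f"pair references unknown target id: {t!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.pairs)

    @property
    def grid_size(self) -> int:
        return len(self.drug_universe) * len(self.target_universe)

    def without_entity(self, entity_id: str, side: str) -> "InteractionSet":
        """Pairs with every interaction involving ``entity_id`` removed."""
        col = 0 if side == "drug" else 1
        kept = [p for p in self.pairs if p[col] != entity_id]
        if not kept:
            raise DataFormatError(
                f"removing {entity_id!r} would leave no interactions")
        return InteractionSet(kept, list(self.drug_universe),
                              list(self.target_universe))


class PairFeaturizer:
    """Builds concatenated drug+target pair vectors from the two feature tables.

    The drug block comes first and the target block second, each in its
    table's column order; shuffling table row order never changes a pair's
    vector because rows are addressed by id.
    """

    def __init__(self, drugs: EntityFeatureTable, targets: EntityFeatureTable):
        if np.isnan(drugs.matrix).any() or np.isnan(targets.matrix).any():
            raise ValueError("pair vectors require fully imputed feature tables")
        self.drugs = drugs
        self.targets = targets
        self.feature_names = (
            [f"d:{n}" for n in drugs.feature_names]
            + [f"t:{n}" for n in targets.feature_names]
        )

    @property
    def n_features(self) -> int:
        return self.drugs.n_features + self.targets.n_features

    def vector(self, drug_id: str, target_id: str) -> np.ndarray:
        return build_pair_vector(self.drugs.row(drug_id),
                                 self.targets.row(target_id))

    def matrix(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        if len(pairs) == 0:
            return np.empty((0, self.n_features))
        d_rows = np.fromiter((self.drugs.index_of(d) for d, _ in pairs),
                             dtype=np.intp, count=len(pairs))
        t_rows = np.fromiter((self.targets.index_of(t) for _, t in pairs),
                             dtype=np.intp, count=len(pairs))
        return np.hstack([self.drugs.matrix[d_rows],
                          self.targets.matrix[t_rows]])


def build_pair_vector(drug_row: np.ndarray, target_row: np.ndarray) -> np.ndarray:
    """Concatenate a drug descriptor vector and a target descriptor vector.

    Output length is the sum of the input lengths; the drug block precedes
    the target block with original feature order preserved.
    """
    drug_row = np.asarray(drug_row, dtype=np.float64).ravel()
    target_row = np.asarray(target_row, dtype=np.float64).ravel()
    return np.concatenate([drug_row, target_row])


# ---------------------------------------------------------------------------
# TSV readers / writers


def load_feature_table(path: str | os.PathLike,
                       delimiter: str = "\t") -> EntityFeatureTable:
    """Parse a feature table TSV with validation of the type invariants.

    Missing cells (``NA`` or empty) are preserved as NaN. A duplicated entity
    id or a non-numeric cell is a hard error naming the offending id and,
    for cells, the row/column.
    """
    header, body = _read_delimited(path, delimiter)
    if len(header) < 2:
        raise DataFormatError(f"{path}: expected an id column plus >=1 feature")
    feature_names = header[1:]
    dup = _first_duplicate(feature_names)
    if dup is not None:
        raise DataFormatError(f"{path}: duplicate feature name {dup!r}")

    ids: list[str] = []
    matrix = np.empty((len(body), len(feature_names)), dtype=np.float64)
    for r, fields in enumerate(body):
        if len(fields) != len(header):
            raise DataFormatError(
                f"{path}: row {r + 1} has {len(fields)} fields, "
                f"expected {len(header)}")
        ids.append(fields[0])
        for c, cell in enumerate(fields[1:]):
            if cell in MISSING_MARKERS:
                matrix[r, c] = np.nan
                continue
            try:
                matrix[r, c] = float(cell)
            except ValueError:
                raise DataFormatError(
                    f"{path}: non-numeric cell {cell!r} at id {fields[0]!r}, "
                    f"feature {feature_names[c]!r}") from None
    dup = _first_duplicate(ids)
    if dup is not None:
        raise DataFormatError(f"{path}: duplicate entity id {dup!r}")
    if np.isinf(matrix).any():
        raise DataFormatError(f"{path}: non-finite feature value")
    return EntityFeatureTable(ids, feature_names, matrix)


def write_feature_table(table: EntityFeatureTable, path: str | os.PathLike,
                        delimiter: str = "\t",
                        header_comments: Iterable[str] = ()) -> None:
    """Write a feature table; re-parsing recovers the matrix bit-exactly.

    Floats are serialised with ``repr`` (shortest round-trip) so the
    parse -> write -> parse cycle is the identity; NaN cells become ``NA``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write(delimiter.join(["id", *table.feature_names]) + "\n")
        for i, entity in enumerate(table.ids):
            cells = [
                "NA" if np.isnan(v) else repr(float(v))
                for v in table.matrix[i]
            ]
            fh.write(delimiter.join([entity, *cells]) + "\n")


def load_interactions(path: str | os.PathLike,
                      drugs: EntityFeatureTable | None = None,
                      targets: EntityFeatureTable | None = None,
                      delimiter: str = "\t") -> InteractionSet:
    """Parse a two-column (drug_id, target_id) interaction list.

    Duplicate rows are dropped. When the feature tables are supplied the
    universes default to the ids present there and any pair referencing an
    id absent from them is a hard error; otherwise the universes are the
    ids observed in the file.
    """
    header, body = _read_delimited(path, delimiter)
    if len(header) != 2:
        raise DataFormatError(
            f"{path}: interaction list must have exactly 2 columns, "
            f"found {len(header)}")
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    for r, fields in enumerate(body):
        if len(fields) != 2:
            raise DataFormatError(f"{path}: row {r + 1} does not have 2 fields")
        pair = (fields[0], fields[1])
        if pair in seen:
            continue
        seen.add(pair)
        pairs.append(pair)
    if not pairs:
        raise DataFormatError(f"{path}: interaction list is empty")

    if drugs is not None and targets is not None:
        for d, t in pairs:
            if d not in drugs:
                raise DataFormatError(
                    f"{path}: pair references drug id {d!r} absent from the "
                    "drug feature table")
            if t not in targets:
                raise DataFormatError(
                    f"{path}: pair references target id {t!r} absent from the "
                    "target feature table")
        drug_universe = list(drugs.ids)
        target_universe = list(targets.ids)
    else:
        drug_universe = list(dict.fromkeys(d for d, _ in pairs))
        target_universe = list(dict.fromkeys(t for _, t in pairs))
    return InteractionSet(pairs, drug_universe, target_universe)


def write_interactions(interactions: InteractionSet, path: str | os.PathLike,
                       delimiter: str = "\t",
                       header_comments: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write(delimiter.join(["drug_id", "target_id"]) + "\n")
        for d, t in interactions.pairs:
            fh.write(delimiter.join([d, t]) + "\n")


def write_predictions(pairs: Sequence[tuple[str, str]],
                      scores: Sequence[float], path: str | os.PathLike,
                      delimiter: str = "\t",
                      header_comments: Iterable[str] = ()) -> None:
    """Write (drug_id, target_id, score) rows sorted by descending score.

    Ties break by ascending (drug_id, target_id) so output is deterministic.
    """
    order = sorted(range(len(pairs)),
                   key=lambda i: (-float(scores[i]), pairs[i][0], pairs[i][1]))
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write(delimiter.join(["drug_id", "target_id", "score"]) + "\n")
        for i in order:
            d, t = pairs[i]
            fh.write(delimiter.join([d, t, repr(float(scores[i]))]) + "\n")


def _read_delimited(path: str | os.PathLike,
                    delimiter: str) -> tuple[list[str], list[list[str]]]:
    if not os.path.exists(path):
        raise DataFormatError(f"input file not found: {path}")
    header: list[str] | None = None
    body: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if header is None:
                header = fields
            else:
                body.append(fields)
    if header is None:
        raise DataFormatError(f"{path}: file has no header row")
    return header, body


def _first_duplicate(items: Iterable) -> object | None:
    seen = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


# ---------------------------------------------------------------------------
# Model serialisation


def save_model(model, path: str | os.PathLike) -> None:
    """Serialise a fitted model with an embedded format-version string."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | os.PathLike):
    """Load a model saved by :func:`save_model`.

    Refuses files whose embedded format version does not match and turns
    truncated/corrupt files into :class:`DataFormatError`.
    """
    if not os.path.exists(path):
        raise DataFormatError(f"model file not found: {path}")
    try:
        payload = joblib.load(path)
    except Exception as exc:  # noqa: BLE001 - any unpickling failure
        raise DataFormatError(f"model file is truncated or corrupt: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise DataFormatError("model file lacks a format-version header")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise DataFormatError(
            f"model format version {payload['format_version']!r} is not "
            f"supported (expected {MODEL_FORMAT_VERSION!r})")
    return payload["model"]
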