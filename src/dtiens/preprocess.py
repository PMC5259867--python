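"""Descriptor cleaning: constant removal, mean imputation, min-max scaling.

The pipeline order is fixed — remove constant features, impute missing
values with the per-feature mean of the observed cells, then min-max
normalise every feature onto [0, 1]. Features whose observed values take
fewer than two distinct values (including all-missing features) carry no
discriminative signal and are dropped up front; this also guarantees the
min-max step never divides by zero. Running the pipeline on its own output
is the identity.

Drug and target tables are always preprocessed independently: scaling
statistics are never pooled across the two entity kinds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import EntityFeatureTable


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessReport:
    """What the pipeline did: removals, imputation counts, scaling params."""

    removed_features: list[str]
    imputed_counts: dict[str, int]
    minmax_params: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        overlap = set(self.removed_features) & set(self.minmax_params)
        if overlap:
            raise PreprocessError(
                f"features both removed and retained: {sorted(overlap)}")
        for name, (lo, hi) in self.minmax_params.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise PreprocessError(f"invalid min-max params for {name!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.removed_features:
            rows.append({"feature": name, "status": "removed",
                         "n_imputed": 0, "min": np.nan, "max": np.nan})
        for name, (lo, hi) in self.minmax_params.items():
            rows.append({"feature": name, "status": "retained",
                         "n_imputed": self.imputed_counts.get(name, 0),
                         "min": lo, "max": hi})
        return pd.DataFrame(rows,
                            columns=["feature", "status", "n_imputed",
                                     "min", "max"])


def remove_constant_features(
        table: EntityFeatureTable) -> tuple[EntityFeatureTable, list[str]]:
    """Drop features with < 2 distinct observed values (incl. all-missing).

    A feature that is constant across every entity cannot contribute to
    discriminating interacting from non-interacting pairs. All-missing
    features are treated the same way: after any imputation they would be
    constant.
    """
    keep: list[int] = []
    removed: list[str] = []
    for j, name in enumerate(table.feature_names):
        col = table.matrix[:, j]
        observed = col[~np.isnan(col)]
        if np.unique(observed).size >= 2:
            keep.append(j)
        else:
            removed.append(name)
    if not keep:
        raise PreprocessError("all features are constant; no usable features")
    kept_names = [table.feature_names[j] for j in keep]
    return (EntityFeatureTable(list(table.ids), kept_names,
                               table.matrix[:, keep].copy()), removed)


def impute_missing_by_mean(
        table: EntityFeatureTable) -> tuple[EntityFeatureTable, dict[str, int]]:
    """Replace each missing cell with the mean of its feature's observed values."""
    matrix = table.matrix.copy()
    counts: dict[str, int] = {}
    for j, name in enumerate(table.feature_names):
        col = matrix[:, j]
        missing = np.isnan(col)
        n_missing = int(missing.sum())
        if n_missing == 0:
            continue
        observed = col[~missing]
        if observed.size == 0:
            raise PreprocessError(
                f"feature {name!r} has no observed values; remove it first")
        col[missing] = observed.mean()
        counts[name] = n_missing
    return EntityFeatureTable(list(table.ids), list(table.feature_names),
                              matrix), counts


def minmax_normalize(
        table: EntityFeatureTable
) -> tuple[EntityFeatureTable, dict[str, tuple[float, float]]]:
    """Map every feature linearly onto [0, 1]; records (min, max) for reuse.

    Per feature f the transform is (f - min f) / (max f - min f), so the
    observed minimum maps to 0 and the maximum to 1. Requires a fully
    imputed table with no constant features.
    """
    if np.isnan(table.matrix).any():
        raise PreprocessError("normalize requires a fully imputed table")
    lo = table.matrix.min(axis=0)
    hi = table.matrix.max(axis=0)
    degenerate = np.where(hi <= lo)[0]
    if degenerate.size:
        name = table.feature_names[int(degenerate[0])]
        raise PreprocessError(
            f"feature {name!r} is constant; remove constants before scaling")
    scaled = (table.matrix - lo) / (hi - lo)
    params = {name: (float(lo[j]), float(hi[j]))
              for j, name in enumerate(table.feature_names)}
    return EntityFeatureTable(list(table.ids), list(table.feature_names),
                              scaled), params


class Preprocessor:
    """Fit-then-transform wrapper around the three cleaning steps.

    By default statistics (feature removals, imputation means, min-max
    bounds) are fitted on the full entity table, matching the study protocol
    of normalising all drugs (resp. targets) before any evaluation split.
    Passing ``fit_entities`` restricts fitting to a subset of entities for
    leakage-free evaluation; transform then applies the stored statistics to
    any entities, clipping values that fall outside the stored [min, max]
    back into [0, 1] so downstream tree thresholds stay in-domain.
    """

    def __init__(self) -> None:
        self.removed_features: list[str] | None = None
        self.retained_features: list[str] | None = None
        self.means_: dict[str, float] | None = None
        self.minmax_params: dict[str, tuple[float, float]] | None = None
        self.report: PreprocessReport | None = None

    def fit(self, table: EntityFeatureTable,
            fit_entities: Sequence[str] | None = None) -> "Preprocessor":
        fit_table = table if fit_entities is None else table.subset(fit_entities)
        cleaned, removed = remove_constant_features(fit_table)
        means = {}
        for j, name in enumerate(cleaned.feature_names):
            col = cleaned.matrix[:, j]
            means[name] = float(col[~np.isnan(col)].mean())
        imputed, counts = impute_missing_by_mean(cleaned)
        _, params = minmax_normalize(imputed)
        self.removed_features = removed
        self.retained_features = list(cleaned.feature_names)
        self.means_ = means
        self.minmax_params = params
        self.report = PreprocessReport(removed, counts, params)
        return self

    def transform(self, table: EntityFeatureTable) -> EntityFeatureTable:
        if self.retained_features is None:
            raise PreprocessError("Preprocessor is not fitted")
        missing_cols = [f for f in self.retained_features
                        if f not in table.feature_names]
        if missing_cols:
            raise PreprocessError(
                f"table lacks fitted features, e.g. {missing_cols[0]!r}")
        col_of = {name: j for j, name in enumerate(table.feature_names)}
        out = np.empty((table.n_entities, len(self.retained_features)))
        for k, name in enumerate(self.retained_features):
            col = table.matrix[:, col_of[name]].copy()
            col[np.isnan(col)] = self.means_[name]
            lo, hi = self.minmax_params[name]
            out[:, k] = np.clip((col - lo) / (hi - lo), 0.0, 1.0)
        return EntityFeatureTable(list(table.ids),
                                  list(self.retained_features), out)

    def fit_transform(self, table: EntityFeatureTable,
                      fit_entities: Sequence[str] | None = None
                      ) -> EntityFeatureTable:
        return self.fit(table, fit_entities).transform(table)


def preprocess_table(
        table: EntityFeatureTable
) -> tuple[EntityFeatureTable, PreprocessReport]:
    """One-shot pipeline: remove constants -> impute -> min-max normalise."""
    pp = Preprocessor()
    out = pp.fit_transform(table)
    return out, pp.report
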