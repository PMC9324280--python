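"""Core data containers and CSV/JSON (de)serialization.

The universal currency of the pipeline is the :class:`FeatureTable`, a
samples x features real matrix with sample/feature identifiers and an
optional binary label vector.  Feature identifiers follow the
``imaging-filter|feature-class|feature-name`` convention, e.g.
``original|shape|SurfaceVolumeRatio``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

__all__ = [
    "FeatureTable",
    "ReplicatePair",
    "ZScoreParams",
    "LinearModelRecord",
    "EnsembleModel",
    "read_feature_table",
    "write_feature_table",
    "serialize_ensemble",
    "deserialize_ensemble",
]


@dataclass
class FeatureTable:
    """Samples x features matrix with IDs and optional 0/1 labels."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None
    cohort_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, d = self.values.shape
        if n != len(self.sample_ids) or d != len(self.feature_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} IDs: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length does not match sample count")
            if not np.isin(self.labels, [0, 1]).all():
                raise ValueError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            [self.sample_ids[i] for i in idx],
            list(self.feature_ids),
            self.values[idx],
            None if self.labels is None else self.labels[idx],
            self.cohort_tag,
        )

    def subset_features(self, feature_ids: list[str]) -> "FeatureTable":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        cols = [pos[f] for f in feature_ids]
        return FeatureTable(
            list(self.sample_ids), list(feature_ids), self.values[:, cols],
            self.labels, self.cohort_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)
        df.index.name = "sample_id"
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df


@dataclass
class ReplicatePair:
    """Primary table plus a repeated-measurement replicate (same IDs, same order)."""

    primary: FeatureTable
    replicate: FeatureTable

    def __post_init__(self) -> None:
        if self.primary.sample_ids != self.replicate.sample_ids:
            raise ValueError("replicate sample IDs differ from primary")
        if self.primary.feature_ids != self.replicate.feature_ids:
            raise ValueError("replicate feature IDs differ from primary")

    def subset_samples(self, idx: np.ndarray) -> "ReplicatePair":
        return ReplicatePair(self.primary.subset_samples(idx), self.replicate.subset_samples(idx))


@dataclass
class ZScoreParams:
    """Per-feature standardization constants (sd strictly positive)."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != self.sds.shape:
            raise ValueError("means/sds length mismatch")
        if np.any(self.sds <= 0):
            raise ValueError("sds must be strictly positive (run variance_filter first)")


@dataclass
class LinearModelRecord:
    """A linear scoring model on a named feature subset, with its Youden cutoff."""

    feature_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    youden_threshold: float
    zscore: ZScoreParams | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.feature_ids) != self.coefficients.shape[0]:
            raise ValueError("coefficients length must equal feature_ids length")

    def score(self, table: FeatureTable) -> np.ndarray:
        x = table.subset_features(self.feature_ids).values
        if self.zscore is not None:
            x = (x - self.zscore.means) / self.zscore.sds
        return x @ self.coefficients + self.intercept


@dataclass
class EnsembleModel:
    """Weighted sum of fold-level linear models with a unit decision threshold.

    Weights are the reciprocal of five times each fold's Youden threshold, so a
    probe scoring exactly ``threshold_i`` on every fold model scores exactly 1.
    """

    fold_models: list[LinearModelRecord]
    weights: np.ndarray
    decision_threshold: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        k = len(self.fold_models)
        if self.weights.shape != (k,):
            raise ValueError("one weight per fold model required")
        for m, w in zip(self.fold_models, self.weights):
            if abs(w * m.youden_threshold - 1.0 / k) > 1e-12:
                raise ValueError("weight_i * threshold_i must equal 1/k")

    @property
    def feature_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.fold_models:
            for f in m.feature_ids:
                seen.setdefault(f)
        return list(seen)

    def score(self, table: FeatureTable) -> np.ndarray:
        total = np.zeros(table.n_samples)
        for m, w in zip(self.fold_models, self.weights):
            total += w * m.score(table)
        return total

    def predict(self, table: FeatureTable, threshold: float | None = None) -> np.ndarray:
        thr = self.decision_threshold if threshold is None else threshold
        return (self.score(table) >= thr).astype(int)


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for s in ids:
        if s in seen:
            dup.add(s)
        seen.add(s)
    return dup


def read_feature_table(
    path: str | Path, label_column: str | None = None, cohort_tag: str = ""
) -> FeatureTable:
    """Load a CSV feature table (first column = sample IDs, header required).

    Raises on duplicate IDs (naming them) and on non-numeric or missing cells
    (naming the coordinates).  Row and column order are preserved.
    """
    df = pd.read_csv(path, header=0, index_col=0, dtype=str, keep_default_na=False)
    sample_ids = [str(s) for s in df.index]
    dupes = _duplicates(sample_ids)
    if dupes:
        raise ValueError(f"duplicate sample IDs in {path}: {sorted(dupes)}")
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in {path}")
        labels = pd.to_numeric(df[label_column], errors="raise").to_numpy()
        df = df.drop(columns=[label_column])
    feature_ids = [str(c) for c in df.columns]
    dupes = _duplicates(feature_ids)
    if dupes:
        raise ValueError(f"duplicate feature IDs in {path}: {sorted(dupes)}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            # pinpoint the offending cell for the error message
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell at sample {sample_ids[i]!r}, "
                        f"feature {col!r}: {cell!r}"
                    ) from None
            raise
    return FeatureTable(sample_ids, feature_ids, values, labels, cohort_tag)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV (inverse of :func:`read_feature_table`)."""
    df = table.to_frame()
    df.to_csv(path, float_format="%.17g")


def _zscore_to_dict(z: ZScoreParams | None):
    if z is None:
        return None
    return {"means": z.means.tolist(), "sds": z.sds.tolist()}


def _zscore_from_dict(d) -> ZScoreParams | None:
    if d is None:
        return None
    return ZScoreParams(np.asarray(d["means"]), np.asarray(d["sds"]))


def serialize_ensemble(model: EnsembleModel, path: str | Path) -> None:
    """Write an :class:`EnsembleModel` as human-diffable JSON.

    Decimal text round-trips through python floats exactly (repr), so all
    coefficients, intercepts, weights and thresholds are preserved
    bit-for-bit.
    """
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "ensemble",
        "provenance": model.provenance,
        "decision_threshold": model.decision_threshold,
        "weights": model.weights.tolist(),
        "fold_models": [
            {
                "feature_ids": m.feature_ids,
                "coefficients": m.coefficients.tolist(),
                "intercept": m.intercept,
                "youden_threshold": m.youden_threshold,
                "zscore": _zscore_to_dict(m.zscore),
            }
            for m in model.fold_models
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def deserialize_ensemble(path: str | Path) -> EnsembleModel:
    """Load an ensemble model JSON; schema mismatches name the missing field."""
    payload = json.loads(Path(path).read_text())
    for key in ("schema_version", "weights", "fold_models", "decision_threshold"):
        if key not in payload:
            raise ValueError(f"ensemble file {path}: missing field {key!r}")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"ensemble file {path}: unsupported schema version "
            f"{payload['schema_version']!r}"
        )
    models = []
    for i, rec in enumerate(payload["fold_models"]):
        for key in ("feature_ids", "coefficients", "intercept", "youden_threshold"):
            if key not in rec:
                raise ValueError(f"ensemble file {path}: fold {i} missing field {key!r}")
        models.append(
            LinearModelRecord(
                rec["feature_ids"],
                np.asarray(rec["coefficients"]),
                float(rec["intercept"]),
                float(rec["youden_threshold"]),
                _zscore_from_dict(rec.get("zscore")),
            )
        )
    return EnsembleModel(
        models,
        np.asarray(payload["weights"]),
        float(payload["decision_threshold"]),
        payload.get("provenance", ""),
    )
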