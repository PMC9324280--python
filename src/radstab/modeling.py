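"""Classifier zoo, stratified cross-validation, ROC/Youden/bootstrap metrics
and the reciprocal-weighted final ensemble.

Workflow: per CV fold, prefilter + selector run on the training split only,
features are Z-score normalized with training-split constants, a classifier
is grid-searched and fitted, and the held-out fold yields the AUC and the
Youden-index operating point.  The five fold-level linear models are then
aggregated with weights ``(threshold_i * 5)^(-1)`` so that the ensemble
decision threshold is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression, Perceptron
from sklearn.svm import LinearSVR
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier

from .data_model import (
    EnsembleModel,
    FeatureTable,
    LinearModelRecord,
    ReplicatePair,
    ZScoreParams,
)
from .prefilter import PrefilterConfig, passing_features, run_prefilter
from .selection import BBRentConfig, select_features

__all__ = [
    "ClassifierSpec",
    "FoldModel",
    "PerfSummary",
    "zscore_fit",
    "zscore_apply",
    "train_classifier",
    "roc_auc",
    "youden_threshold",
    "bootstrap_ci",
    "stratified_fold_indices",
    "cross_validate",
    "build_ensemble",
    "recalibrate_threshold",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("svr-linear", "logistic", "random-forest", "perceptron", "knn")

_DEFAULT_GRIDS = {
    "svr-linear": {"C": [0.1, 1.0, 10.0]},
    "logistic": {"C": [0.1, 1.0, 10.0]},
    "random-forest": {"n_estimators": [100, 300], "max_depth": [None, 10]},
    "perceptron": {"alpha": [1e-4, 1e-3]},
    "knn": {"n_neighbors": [5, 11, 21]},
}


@dataclass
class ClassifierSpec:
    kind: str = "svr-linear"
    grid: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; choose from {CLASSIFIER_KINDS}")
        if self.grid is None:
            self.grid = dict(_DEFAULT_GRIDS[self.kind])


class _ScoredModel:
    """Wraps a fitted sklearn estimator with a 'larger = more positive' score."""

    def __init__(self, kind: str, est):
        self.kind = kind
        self.est = est

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "svr-linear":
            return self.est.predict(X)
        if self.kind == "logistic":  # binary predictions by design
            return self.est.predict(X).astype(float)
        if self.kind == "random-forest":
            return self.est.predict_proba(X)[:, 1]
        if self.kind == "perceptron":  # bounded score via logistic squash
            return expit(self.est.decision_function(X))
        if self.kind == "knn":  # positive-neighbor fraction
            return self.est.predict_proba(X)[:, 1]
        raise AssertionError(self.kind)

    def linear_record(
        self, feature_ids: list[str], youden: float, zscore: ZScoreParams | None
    ) -> LinearModelRecord:
        if self.kind not in ("svr-linear", "logistic"):
            raise ValueError(f"classifier kind {self.kind!r} has no linear form")
        coef = np.ravel(self.est.coef_)
        intercept = float(np.ravel(self.est.intercept_)[0])
        return LinearModelRecord(list(feature_ids), coef, intercept, youden, zscore)


@dataclass
class FoldModel:
    fold: int
    feature_ids: list[str]
    zscore: ZScoreParams
    model: _ScoredModel
    auc: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    accuracy: float

    def score(self, table: FeatureTable) -> np.ndarray:
        x = table.subset_features(self.feature_ids).values
        return self.model.score_samples(zscore_apply(x, self.zscore))


@dataclass
class PerfSummary:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    ci: dict = field(default_factory=dict)  # metric -> (lo, hi)
    threshold: float = np.nan
    threshold_origin: str = ""
    flags: list[str] = field(default_factory=list)


def zscore_fit(X: np.ndarray) -> ZScoreParams:
    X = np.asarray(X, float)
    sds = X.std(axis=0, ddof=0)
    if np.any(sds <= 0):
        j = int(np.argmax(sds <= 0))
        raise ValueError(f"feature column {j} is constant; run variance_filter first")
    return ZScoreParams(X.mean(axis=0), sds)


def zscore_apply(X: np.ndarray, params: ZScoreParams) -> np.ndarray:
    return (np.asarray(X, float) - params.means) / params.sds


def _make_estimator(kind: str, params: dict, seed: int):
    if kind == "svr-linear":
        return LinearSVR(C=params["C"], max_iter=50000, random_state=seed)
    if kind == "logistic":
        return LogisticRegression(C=params["C"], max_iter=5000, random_state=seed)
    if kind == "random-forest":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"], max_depth=params["max_depth"],
            random_state=seed, n_jobs=1,
        )
    if kind == "perceptron":
        return Perceptron(alpha=params["alpha"], random_state=seed)
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=params["n_neighbors"])
    raise AssertionError(kind)


def train_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> _ScoredModel:
    """Grid search (internal stratified 3-fold CV on AUC) then refit on all data."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    keys = sorted(spec.grid)
    combos = [dict(zip(keys, vals)) for vals in product(*(spec.grid[k] for k in keys))]
    best_params, best_auc = combos[0], -np.inf
    if len(combos) > 1:
        folds = stratified_fold_indices(y, k=3, seed=spec.seed)
        for params in combos:
            aucs = []
            for f in folds:
                mask = np.ones(len(y), bool)
                mask[f] = False
                if len(np.unique(y[mask])) < 2 or len(np.unique(y[f])) < 2:
                    continue
                m = _ScoredModel(spec.kind, _make_estimator(spec.kind, params, spec.seed))
                m.est.fit(X[mask], y[mask] if spec.kind != "svr-linear" else y[mask].astype(float))
                aucs.append(roc_auc(m.score_samples(X[f]), y[f]))
            mean_auc = float(np.mean(aucs)) if aucs else -np.inf
            if mean_auc > best_auc + 1e-12:
                best_auc, best_params = mean_auc, params
    model = _ScoredModel(spec.kind, _make_estimator(spec.kind, best_params, spec.seed))
    model.est.fit(X, y if spec.kind != "svr-linear" else y.astype(float))
    return model


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney concordance probability with ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes required to compute AUC")
    from scipy.stats import rankdata

    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Maximize J = sensitivity + specificity - 1 over candidate thresholds.

    Candidates are the unique score values; decision rule is
    ``score >= threshold -> class 1``; ties go to the smallest maximizing
    threshold.  Returns ``(threshold, sensitivity, specificity)``.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    best = None
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = float(pred[labels == 1].mean())
        spec = float((~pred)[labels == 0].mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(thr), sens, spec)
    _, thr, sens, spec = best
    return thr, sens, spec


def bootstrap_ci(
    metric,
    scores: np.ndarray,
    labels: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float, int]:
    """Class-stratified percentile bootstrap CI for ``metric(scores, labels)``.

    Resamples on which the metric is undefined are redrawn; returns
    ``(point, lo, hi, n_redrawn)``.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    point = float(metric(scores, labels))
    rng = np.random.default_rng(seed)
    idx_by_class = [np.where(labels == c)[0] for c in (0, 1)]
    vals = np.empty(B)
    redrawn = 0
    for b in range(B):
        for _ in range(100):
            idx = np.concatenate(
                [rng.choice(ic, size=len(ic), replace=True) for ic in idx_by_class]
            )
            try:
                vals[b] = float(metric(scores[idx], labels[idx]))
                break
            except (ValueError, ZeroDivisionError):
                redrawn += 1
        else:
            raise RuntimeError("metric undefined on 100 consecutive resamples")
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return point, float(lo), float(hi), redrawn


def stratified_fold_indices(y: np.ndarray, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Maximally balanced stratified k-fold assignment.

    Each class is shuffled and dealt round-robin; per-class remainders go to
    the folds with the smallest current totals, so 442 balanced samples
    split as 89/89/88/88/88.
    """
    y = np.asarray(y, int)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(y):
        members = rng.permutation(np.where(y == c)[0])
        base, extra = divmod(len(members), k)
        # folds currently smallest take the extras, ties broken by index
        order = sorted(range(k), key=lambda f: (len(folds[f]), f))
        take = {order[i]: base + 1 if i < extra else base for i in range(k)}
        start = 0
        for f in range(k):
            folds[f].extend(members[start : start + take[f]])
            start += take[f]
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def cross_validate(
    pair: ReplicatePair,
    labels: np.ndarray | None = None,
    spec: ClassifierSpec | None = None,
    selector_config: BBRentConfig | None = None,
    prefilter_config: PrefilterConfig | None = None,
    selector_method: str = "bb-rent",
    k: int = 5,
    seed: int = 0,
) -> tuple[list[FoldModel], list[PerfSummary], PerfSummary]:
    """Stratified k-fold CV of the full pipeline.

    Per fold: prefilter and feature selection on the training split only,
    Z-score fit on the training split, classifier grid-searched and trained,
    then AUC and the Youden operating point computed on the held-out fold.
    Returns (fold models, per-fold summaries, mean summary).
    """
    labels = pair.primary.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise ValueError("labels are required")
    spec = spec or ClassifierSpec()
    selector_config = selector_config or BBRentConfig()
    folds = stratified_fold_indices(labels, k=k, seed=seed)
    n = len(labels)
    fold_models: list[FoldModel] = []
    summaries: list[PerfSummary] = []
    for i, hold in enumerate(folds):
        mask = np.ones(n, bool)
        mask[hold] = False
        train_idx = np.where(mask)[0]
        train_pair = pair.subset_samples(train_idx)
        y_tr, y_ho = labels[train_idx], labels[hold]
        report = run_prefilter(train_pair, y_tr, prefilter_config)
        kept = passing_features(report)
        if not kept:
            raise RuntimeError(f"fold {i}: no features survive the prefilter")
        x_tr = train_pair.primary.subset_features(kept).values
        zs_sel = zscore_fit(x_tr)
        cfg_i = replace(selector_config, seed=int(selector_config.seed + 1000 * i))
        sel = select_features(
            selector_method, zscore_apply(x_tr, zs_sel), y_tr, kept, cfg_i
        ).selected
        if not sel:  # selector too strict on this fold: fall back to prefilter set
            sel = kept
        x_tr_sel = train_pair.primary.subset_features(sel).values
        zs = zscore_fit(x_tr_sel)
        model = train_classifier(replace(spec, seed=spec.seed + i), zscore_apply(x_tr_sel, zs), y_tr)
        ho_table = pair.primary.subset_samples(hold).subset_features(sel)
        scores = model.score_samples(zscore_apply(ho_table.values, zs))
        auc = roc_auc(scores, y_ho)
        thr, sens, spc = youden_threshold(scores, y_ho)
        pred = scores >= thr
        acc = float((pred == (y_ho == 1)).mean())
        fold_models.append(FoldModel(i, sel, zs, model, auc, thr, sens, spc, acc))
        summaries.append(
            PerfSummary(auc, acc, sens, spc, threshold=thr, threshold_origin=f"fold-{i}-youden")
        )
    mean = PerfSummary(
        float(np.mean([s.auc for s in summaries])),
        float(np.mean([s.accuracy for s in summaries])),
        float(np.mean([s.sensitivity for s in summaries])),
        float(np.mean([s.specificity for s in summaries])),
        threshold=float(np.mean([s.threshold for s in summaries])),
        threshold_origin="mean-fold-youden",
    )
    return fold_models, summaries, mean


def build_ensemble(fold_models: list[FoldModel], provenance: str = "") -> EnsembleModel:
    """Aggregate fold models with weights ``(threshold_i * k)^(-1)``.

    Requires linear fold models with positive Youden thresholds (score
    orientation: larger = positive class).
    """
    k = len(fold_models)
    records, weights = [], []
    for fm in fold_models:
        if not np.isfinite(fm.youden_threshold) or fm.youden_threshold <= 0:
            raise ValueError(
                f"fold {fm.fold}: non-positive Youden threshold "
                f"{fm.youden_threshold}; score orientation violated"
            )
        records.append(fm.model.linear_record(fm.feature_ids, fm.youden_threshold, fm.zscore))
        weights.append(1.0 / (fm.youden_threshold * k))
    return EnsembleModel(records, np.asarray(weights), 1.0, provenance)


def _threshold_summary(scores, labels, thr, origin, B=1000, seed=0) -> PerfSummary:
    labels = np.asarray(labels, int)
    pred = scores >= thr
    sens = float(pred[labels == 1].mean())
    spec = float((~pred)[labels == 0].mean())
    acc = float((pred == (labels == 1)).mean())
    auc, lo, hi, _ = bootstrap_ci(roc_auc, scores, labels, B=B, seed=seed)
    ci = {"auc": (lo, hi)}
    for name, fn in (
        ("sensitivity", lambda s, l: float((s >= thr)[l == 1].mean())),
        ("specificity", lambda s, l: float((s < thr)[l == 0].mean())),
        ("accuracy", lambda s, l: float(((s >= thr) == (l == 1)).mean())),
    ):
        _, lo, hi, _ = bootstrap_ci(fn, scores, labels, B=B, seed=seed)
        ci[name] = (lo, hi)
    flags = []
    if spec == 0.0:
        flags.append("degenerate: specificity 0 at this threshold")
    if sens == 0.0:
        flags.append("degenerate: sensitivity 0 at this threshold")
    return PerfSummary(auc, acc, sens, spec, ci, thr, origin, flags)


def recalibrate_threshold(
    model: EnsembleModel,
    cohort: FeatureTable,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, PerfSummary, PerfSummary]:
    """Recompute the Youden threshold on a new labeled cohort.

    Returns ``(new_threshold, summary_at_normalized, summary_at_recalibrated)``
    where the normalized threshold is the ensemble's unit decision threshold.
    """
    if cohort.labels is None:
        raise ValueError("cohort must be labeled for recalibration")
    scores = model.score(cohort)
    new_thr, _, _ = youden_threshold(scores, cohort.labels)
    at_norm = _threshold_summary(
        scores, cohort.labels, model.decision_threshold, "training-normalized", B, seed
    )
    at_recal = _threshold_summary(scores, cohort.labels, new_thr, "recalibrated-youden", B, seed)
    return float(new_thr), at_norm, at_recal
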