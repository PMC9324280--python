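"""Supervised feature selection: elastic net, boosted elastic net, the
repeated-elastic-net (RENT) criteria, and the bagged-boosted selector.

The selector family (method tags used throughout the package):

- ``enet``          a single elastic-net fit; selected = nonzero coefficients
- ``rent``          K resampled elastic nets sieved by three coefficient
                    criteria (nonzero frequency, sign stability, t-test)
- ``boosted-rent``  RENT with each fit replaced by an AdaBoost chain of
                    elastic nets (aggregated, boost-weighted coefficients)
- ``bagged-rent``   RENT wrapped in Q bootstrap bags, keeping features
                    nominated in more than eta*Q bags
- ``bb-rent``       boosted RENT wrapped in the same bagging layer

Default full-scale hyperparameters are N=25 boosting rounds, K=200 RENT
repetitions, Q=150 bags and eta=0.5; tests and examples run at reduced
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._enet import enet_logistic

__all__ = [
    "EnetConfig",
    "RentCriteria",
    "BoostedEnet",
    "BBRentConfig",
    "SelectionResult",
    "fit_elastic_net",
    "fit_boosted_enet",
    "rent_select",
    "bb_rent",
    "single_enet_select",
    "select_features",
    "METHODS",
]

METHODS = ("enet", "rent", "boosted-rent", "bagged-rent", "bb-rent")


@dataclass
class EnetConfig:
    """Elastic-net penalized logistic regression settings.

    ``reg_strength`` is the penalty on the mean-loss scale; ``"auto"``
    resolves it once per selector invocation by internal 5-fold CV.
    """

    l1_ratio: float = 0.5
    reg_strength: float | str = "auto"
    max_iter: int = 2000
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if not (0.0 <= self.l1_ratio <= 1.0):
            raise ValueError("l1_ratio must lie in [0, 1]")
        if self.reg_strength != "auto" and not float(self.reg_strength) > 0:
            raise ValueError("reg_strength must be positive or 'auto'")


@dataclass
class RentCriteria:
    """Cutoffs for the three per-feature coefficient criteria."""

    tau1: float = 0.9          # min empirical nonzero frequency
    tau2: float = 0.9          # min sign-stability rate
    tau3: float = 0.05         # max p for the one-sample t-test on weights
    K: int = 200
    subsample_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau1 <= 1.0 and 0.0 <= self.tau2 <= 1.0):
            raise ValueError("tau1/tau2 must lie in [0, 1]")
        if not (0.0 < self.tau3 < 1.0):
            raise ValueError("tau3 must lie in (0, 1)")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must lie in (0, 1]")


@dataclass
class BoostedEnet:
    """An AdaBoost chain of elastic nets with aggregated coefficients."""

    learners: list[tuple[np.ndarray, float]]
    boost_weights: np.ndarray
    aggregated_coeffs: np.ndarray
    aggregated_intercept: float
    fallback: bool = False
    weighted_errors: list[float] = field(default_factory=list)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.aggregated_coeffs + self.aggregated_intercept


@dataclass
class BBRentConfig:
    """Hyperparameters of the bagged-boosted selector."""

    N: int = 25
    K: int = 200
    Q: int = 150
    eta: float = 0.5
    criteria: RentCriteria = field(default_factory=RentCriteria)
    enet: EnetConfig = field(default_factory=EnetConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.N, self.K, self.Q) < 1:
            raise ValueError("N, K, Q must be >= 1")
        if not (0.0 < self.eta < 1.0):
            raise ValueError("eta must lie in (0, 1)")
        self.criteria = replace(self.criteria, K=self.K)


@dataclass
class SelectionResult:
    """Selected feature IDs plus per-feature diagnostics."""

    selected: list[str]
    diagnostics: pd.DataFrame  # c1, c2, c3 (+ nomination_count for bagged methods)
    method: str

    def __post_init__(self) -> None:
        missing = set(self.selected) - set(self.diagnostics.index)
        if missing:
            raise ValueError(f"selected features missing from diagnostics: {missing}")


def _resolve_lambda(X, y, cfg: EnetConfig, seed: int = 0) -> float:
    """Internal stratified 5-fold CV over a geometric grid anchored at the
    smallest penalty that zeroes every coefficient (lambda_max).

    Uses the 1-SE rule: the largest penalty whose CV AUC is within one
    standard error of the best, so null data resolves to heavy shrinkage.
    """
    if cfg.reg_strength != "auto":
        return float(cfg.reg_strength)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    pbar = y.mean()
    grad0 = X.T @ (y - pbar) / n  # gradient of mean log-loss at w=0 (up to sign)
    lam_max = np.abs(grad0).max() / max(cfg.l1_ratio, 1e-3)
    grid = lam_max * np.asarray([1.0, 0.5, 0.3, 0.2, 0.1, 0.05])
    rng = np.random.default_rng(seed)
    order = np.concatenate([rng.permutation(np.where(y == c)[0]) for c in (0, 1)])
    folds = [order[i::5] for i in range(5)]
    means, ses = [], []
    for lam in grid:
        aucs = []
        for f in folds:
            mask = np.ones(n, bool)
            mask[f] = False
            if len(np.unique(y[f])) < 2 or len(np.unique(y[mask])) < 2:
                continue
            w, b, _ = enet_logistic(
                X[mask], y[mask], lam, cfg.l1_ratio, max_iter=cfg.max_iter, tol=cfg.tol
            )
            s = X[f] @ w + b
            aucs.append(_fast_auc(s, y[f]))
        means.append(np.mean(aucs) if aucs else -np.inf)
        ses.append(np.std(aucs, ddof=1) / np.sqrt(len(aucs)) if len(aucs) > 1 else 0.0)
    best = int(np.argmax(means))
    # no-signal guard: if even the best CV AUC is not credibly above chance,
    # resolve to full shrinkage rather than chase noise
    if means[best] - 4.0 * ses[best] <= 0.5:
        return float(grid[0])
    cutoff = means[best] - ses[best]
    for lam, m in zip(grid, means):  # grid is descending: first hit = largest lam
        if m >= cutoff:
            return float(lam)
    return float(grid[best])


def _fast_auc(scores, labels) -> float:
    r = stats.rankdata(scores)
    n1 = int(np.sum(labels == 1))
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        return 0.5
    return (r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1)


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    cfg: EnetConfig | None = None,
    sample_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Minimize the elastic-net penalized logistic loss; deterministic.

    Emits a warning (and returns the last iterate) on non-convergence.
    """
    cfg = cfg or EnetConfig()
    lam = _resolve_lambda(X, y, cfg)
    w, b, ok = enet_logistic(
        X, y, lam, cfg.l1_ratio, sample_weights, cfg.max_iter, cfg.tol
    )
    if not ok:
        warnings.warn("elastic net did not converge within max_iter", RuntimeWarning)
    return w, b


def fit_boosted_enet(
    X: np.ndarray,
    y: np.ndarray,
    cfg: EnetConfig | None = None,
    N: int = 25,
    lam: float | None = None,
) -> BoostedEnet:
    """Discrete two-class AdaBoost over elastic-net weak learners.

    Each round fits on the current sample weights, computes the weighted
    0/1 error ``eps`` of the thresholded predictions, sets the boost weight
    ``beta = 0.5 * ln((1 - eps) / eps)`` and reweights samples.  The chain
    stops early on ``eps = 0`` or ``eps >= 0.5``; if the *first* learner has
    ``eps >= 0.5`` the result falls back to that single learner with unit
    weight (``fallback`` flag set).  Aggregated coefficients are the
    boost-weight-normalized combination of the weak learners.
    """
    cfg = cfg or EnetConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = X.shape[0]
    if lam is None:
        lam = _resolve_lambda(X, y, cfg)
    c = np.full(n, 1.0 / n)
    t = 2.0 * y - 1.0
    learners: list[tuple[np.ndarray, float]] = []
    betas: list[float] = []
    epsilons: list[float] = []
    fallback = False
    for m in range(N):
        # m = 0 takes the unweighted path so that an N=1 chain is bit-identical
        # to a plain elastic-net fit
        w, b, _ = enet_logistic(
            X, y, lam, cfg.l1_ratio, c if m else None, cfg.max_iter, cfg.tol
        )
        pred = np.where(X @ w + b >= 0.0, 1.0, -1.0)
        eps = float(c[pred != t].sum())
        if eps >= 0.5:
            if m == 0:
                learners.append((w, b))
                betas.append(1.0)
                epsilons.append(eps)
                fallback = True
            break
        eps_c = max(eps, 1e-12)
        beta = 0.5 * np.log((1.0 - eps_c) / eps_c)
        learners.append((w, b))
        betas.append(beta)
        epsilons.append(eps)
        if eps == 0.0:
            break
        c = c * np.exp(-beta * t * pred)
        c /= c.sum()
    bw = np.asarray(betas)
    norm = bw / bw.sum()
    agg_w = sum(g * wl for g, (wl, _) in zip(norm, learners))
    agg_b = float(sum(g * bl for g, (_, bl) in zip(norm, learners)))
    return BoostedEnet(learners, bw, np.asarray(agg_w), agg_b, fallback, epsilons)


def _stratified_subsample(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Without-replacement subsample keeping each class's share (>=1 each)."""
    idx = []
    for c in (0, 1):
        members = np.where(y == c)[0]
        take = max(1, int(round(fraction * len(members))))
        idx.append(rng.choice(members, size=min(take, len(members)), replace=False))
    return np.sort(np.concatenate(idx))


def rent_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    criteria: RentCriteria | None = None,
    boosted: bool = False,
    enet_cfg: EnetConfig | None = None,
    N: int = 25,
    seed: int = 0,
) -> SelectionResult:
    """RENT: K subsampled (boosted) elastic nets sieved by three criteria.

    Per feature over the K aggregated coefficient vectors ``w^(k)``:
    ``c1`` = fraction of runs with a nonzero weight; ``c2`` = dominant-sign
    rate among nonzero weights (1.0 when never nonzero — such features fail
    ``c1`` anyway); ``c3`` = two-sided one-sample t-test p-value against
    zero mean weight.  Selected iff ``c1 >= tau1 and c2 >= tau2 and
    c3 <= tau3``.
    """
    criteria = criteria or RentCriteria()
    enet_cfg = enet_cfg or EnetConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    lam = _resolve_lambda(X, y, enet_cfg, seed=seed)
    K = criteria.K
    W = np.empty((K, X.shape[1]))
    for k in range(K):
        idx = _stratified_subsample(y, criteria.subsample_fraction, rng)
        Xs, ys = X[idx], y[idx]
        if boosted:
            W[k] = fit_boosted_enet(Xs, ys, enet_cfg, N=N, lam=lam).aggregated_coeffs
        else:
            w, _, _ = enet_logistic(
                Xs, ys, lam, enet_cfg.l1_ratio, None, enet_cfg.max_iter, enet_cfg.tol
            )
            W[k] = w
    nz = W != 0.0
    c1 = nz.mean(axis=0)
    npos = (W > 0).sum(axis=0)
    nneg = (W < 0).sum(axis=0)
    nnz = nz.sum(axis=0)
    with np.errstate(invalid="ignore"):
        c2 = np.where(nnz > 0, np.maximum(npos, nneg) / np.maximum(nnz, 1), 1.0)
    c3 = np.ones(X.shape[1])
    varying = W.std(axis=0) > 0
    if varying.any():
        c3[varying] = stats.ttest_1samp(W[:, varying], 0.0, axis=0).pvalue
    # constant nonzero column: zero variance but clearly nonzero mean
    const_nz = (~varying) & (nnz == K)
    c3[const_nz] = 0.0
    keep = (c1 >= criteria.tau1) & (c2 >= criteria.tau2) & (c3 <= criteria.tau3)
    diag = pd.DataFrame(
        {"c1": c1, "c2": c2, "c3": c3}, index=pd.Index(feature_ids, name="feature_id")
    )
    selected = [f for f, k in zip(feature_ids, keep) if k]
    return SelectionResult(selected, diag, "boosted-rent" if boosted else "rent")


def _stratified_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """With-replacement resample of original size; redrawn (up to 100x) if a
    class vanishes, which only matters at degenerate sizes."""
    n = len(y)
    for _ in range(100):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) == 2:
            return idx
    raise RuntimeError("could not draw a bootstrap containing both classes")


def bb_rent(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    cfg: BBRentConfig | None = None,
    boosted: bool = True,
) -> SelectionResult:
    """Bagged (boosted) RENT.

    The data are bootstrapped Q times; each bag runs (boosted) RENT, and a
    feature is ultimately selected iff its nomination count is strictly
    greater than ``eta * Q``.  ``boosted=False`` gives the bagged-RENT
    comparator.
    """
    cfg = cfg or BBRentConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    # resolve the penalty once on the full data and reuse it in every bag
    lam = _resolve_lambda(X, y, cfg.enet, seed=cfg.seed)
    enet_cfg = replace(cfg.enet, reg_strength=lam)
    ss = np.random.SeedSequence(cfg.seed)
    bag_seeds = ss.generate_state(cfg.Q + 1)
    rng = np.random.default_rng(bag_seeds[-1])
    counts = np.zeros(len(feature_ids), dtype=int)
    for q in range(cfg.Q):
        if cfg.Q == 1:
            idx = np.arange(len(y))  # degenerate bagging: use the data as-is
        else:
            idx = _stratified_bootstrap(y, rng)
        res = rent_select(
            X[idx], y[idx], feature_ids, cfg.criteria, boosted, enet_cfg,
            N=cfg.N, seed=int(bag_seeds[q]),
        )
        sel = set(res.selected)
        counts += np.fromiter((f in sel for f in feature_ids), dtype=int)
    keep = counts > cfg.eta * cfg.Q
    diag = pd.DataFrame(
        {"nomination_count": counts, "nomination_frequency": counts / cfg.Q},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    selected = [f for f, k in zip(feature_ids, keep) if k]
    return SelectionResult(selected, diag, "bb-rent" if boosted else "bagged-rent")


def single_enet_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    enet_cfg: EnetConfig | None = None,
) -> SelectionResult:
    """Baseline: features with nonzero coefficients in one elastic-net fit."""
    w, _ = fit_elastic_net(X, y, enet_cfg)
    diag = pd.DataFrame(
        {"coefficient": w}, index=pd.Index(feature_ids, name="feature_id")
    )
    selected = [f for f, wi in zip(feature_ids, w) if wi != 0.0]
    return SelectionResult(selected, diag, "enet")


def select_features(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    cfg: BBRentConfig | None = None,
) -> SelectionResult:
    """Dispatch on the five selector variants by method tag."""
    cfg = cfg or BBRentConfig()
    if method == "enet":
        return single_enet_select(X, y, feature_ids, cfg.enet)
    if method == "rent":
        return rent_select(
            X, y, feature_ids, cfg.criteria, False, cfg.enet, cfg.N, cfg.seed
        )
    if method == "boosted-rent":
        return rent_select(
            X, y, feature_ids, cfg.criteria, True, cfg.enet, cfg.N, cfg.seed
        )
    if method == "bagged-rent":
        return bb_rent(X, y, feature_ids, cfg, boosted=False)
    if method == "bb-rent":
        return bb_rent(X, y, feature_ids, cfg, boosted=True)
    raise ValueError(f"unknown selection method {method!r}; choose from {METHODS}")
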