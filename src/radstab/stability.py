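"""Feature-selection stability: Jaccard index, the Nogueira variance-based
stability estimator with its asymptotic hypothesis test, and the resampling
experiment comparing selector variants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ReplicatePair
from .prefilter import PrefilterConfig, passing_features, run_prefilter
from .selection import BBRentConfig, select_features

__all__ = [
    "SelectionRunSet",
    "jaccard",
    "mean_pairwise_jaccard",
    "nogueira_score",
    "nogueira_variance",
    "nogueira_test",
    "stability_experiment",
]


@dataclass
class SelectionRunSet:
    """M selected feature sets from one method over resampling runs."""

    method: str
    runs: list[set[str]]
    pool: list[str]

    def __post_init__(self) -> None:
        if len(self.runs) < 2:
            raise ValueError("need at least 2 runs")
        pool = set(self.pool)
        for i, r in enumerate(self.runs):
            extra = set(r) - pool
            if extra:
                raise ValueError(f"run {i} selects features outside the pool: {extra}")

    @property
    def M(self) -> int:
        return len(self.runs)

    @property
    def d(self) -> int:
        return len(self.pool)

    def binary_matrix(self) -> np.ndarray:
        """M x d 0/1 selection matrix in pool order."""
        z = np.zeros((self.M, self.d), dtype=float)
        pos = {f: j for j, f in enumerate(self.pool)}
        for i, r in enumerate(self.runs):
            for f in r:
                z[i, pos[f]] = 1.0
        return z


def jaccard(a: set[str], b: set[str]) -> float:
    """|a n b| / |a u b|; 1.0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def mean_pairwise_jaccard(runs: SelectionRunSet) -> tuple[float, float, np.ndarray]:
    """Mean and sd (ddof=1) over all C(M,2) unordered pair Jaccard values."""
    vals = np.asarray([jaccard(a, b) for a, b in combinations(runs.runs, 2)])
    return float(vals.mean()), float(vals.std(ddof=1)), vals


def nogueira_score(runs: SelectionRunSet) -> float:
    """Variance-based stability over the M x d binary selection matrix.

    ``Phi = 1 - mean_f(s_f^2) / (kbar/d * (1 - kbar/d))`` with the unbiased
    per-feature selection variance ``s_f^2 = M/(M-1) * p_f (1 - p_f)`` and
    ``kbar`` the mean subset size.  1 for a constant non-trivial selector,
    ~0 for uniform random selection; undefined for always-empty or
    always-full selection.
    """
    z = runs.binary_matrix()
    return _phi(z)


def _phi(z: np.ndarray) -> float:
    m, d = z.shape
    p = z.mean(axis=0)
    kbar = p.sum()
    denom = (kbar / d) * (1.0 - kbar / d)
    if denom == 0.0:
        raise ValueError("stability undefined for trivial selectors (kbar in {0, d})")
    s2 = m / (m - 1.0) * p * (1.0 - p)
    return float(1.0 - s2.mean() / denom)


def nogueira_variance(runs: SelectionRunSet) -> float:
    """Asymptotic variance estimate of the stability estimator.

    Delta-method estimate: ``v = 4/M^2 * sum_i (phi_i - mean(phi))^2`` with
    per-run influence terms

    ``phi_i = (1/denom) * [ mean_f(z_if p_f) - k_i kbar / d^2
              - (Phi/2) * (2 k_i kbar / d^2 - k_i/d - kbar/d + 1) ]``.
    """
    z = runs.binary_matrix()
    m, d = z.shape
    p = z.mean(axis=0)
    kbar = p.sum()
    k = z.sum(axis=1)
    denom = (kbar / d) * (1.0 - kbar / d)
    if denom == 0.0:
        raise ValueError("stability undefined for trivial selectors (kbar in {0, d})")
    phi_hat = _phi(z)
    phi_i = (1.0 / denom) * (
        (z * p).mean(axis=1)
        - k * kbar / d**2
        - (phi_hat / 2.0) * (2.0 * k * kbar / d**2 - k / d - kbar / d + 1.0)
    )
    return float(4.0 / m**2 * np.sum((phi_i - phi_i.mean()) ** 2))


def nogueira_test(runs_a: SelectionRunSet, runs_b: SelectionRunSet) -> tuple[float, float]:
    """Two-population z-test on the difference of stability estimates.

    ``z = (Phi_a - Phi_b) / sqrt(v_a + v_b)`` against a standard normal;
    returns ``(z, two-sided p)``.  ``z = 0, p = 1`` when both run sets are
    identical.
    """
    if set(runs_a.pool) != set(runs_b.pool):
        raise ValueError("run sets must share the same feature pool")
    pa, pb = _phi(runs_a.binary_matrix()), _phi(runs_b.binary_matrix())
    va, vb = nogueira_variance(runs_a), nogueira_variance(runs_b)
    denom = np.sqrt(va + vb)
    if denom == 0.0:
        if pa == pb:
            return 0.0, 1.0
        return float(np.sign(pa - pb) * np.inf), 0.0
    z = (pa - pb) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def stability_experiment(
    pair: ReplicatePair,
    labels: np.ndarray | None = None,
    methods: tuple[str, ...] = ("enet", "rent", "boosted-rent", "bagged-rent", "bb-rent"),
    M: int = 100,
    fraction: float = 0.8,
    seed: int = 0,
    prefilter_config: PrefilterConfig | None = None,
    selector_config: BBRentConfig | None = None,
    selector: "callable | None" = None,
) -> dict:
    """Resample ``fraction`` of the samples (without replacement) M times and
    run prefilter + each selector on every subsample (the subsample is shared
    across methods within a run, i.e. a paired design).

    Returns a dict with per-method :class:`SelectionRunSet`, a Table-5-shaped
    summary frame (mean subset size, mean pairwise Jaccard +- sd, stability
    score), and pairwise comparisons: unpaired and paired t-tests on the
    Jaccard values plus the stability z-test.

    ``selector(method, X, y, feature_ids, cfg, run_index)`` can override the
    selection call (used for mock selectors in tests).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    labels = pair.primary.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise ValueError("labels are required")
    selector_config = selector_config or BBRentConfig()
    pool = list(pair.primary.feature_ids)
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.generate_state(M)
    run_sets: dict[str, list[set[str]]] = {m: [] for m in methods}
    sizes: dict[str, list[int]] = {m: [] for m in methods}
    for i in range(M):
        rng = np.random.default_rng(run_seeds[i])
        idx = np.sort(
            np.concatenate(
                [
                    rng.choice(
                        np.where(labels == c)[0],
                        size=max(1, int(round(fraction * np.sum(labels == c)))),
                        replace=False,
                    )
                    for c in (0, 1)
                ]
            )
        )
        sub = pair.subset_samples(idx)
        y = labels[idx]
        report = run_prefilter(sub, y, prefilter_config)
        kept = passing_features(report)
        for method in methods:
            if selector is not None:
                sel = selector(method, sub, y, kept, selector_config, i)
            elif not kept:
                sel = []
            else:
                x = sub.primary.subset_features(kept).values
                mu, sd = x.mean(axis=0), x.std(axis=0, ddof=1)
                xz = (x - mu) / sd
                cfg_i = replace(selector_config, seed=int(run_seeds[i]))
                sel = select_features(method, xz, y, kept, cfg_i).selected
            run_sets[method].append(set(sel))
            sizes[method].append(len(sel))

    result_sets = {m: SelectionRunSet(m, run_sets[m], pool) for m in methods}
    summary_rows = []
    jac_values: dict[str, np.ndarray] = {}
    for m in methods:
        jmean, jsd, jvals = mean_pairwise_jaccard(result_sets[m])
        jac_values[m] = jvals
        try:
            phi = nogueira_score(result_sets[m])
        except ValueError:
            phi = np.nan
        summary_rows.append(
            {
                "method": m,
                "mean_n_features": float(np.mean(sizes[m])),
                "sd_n_features": float(np.std(sizes[m], ddof=1)),
                "mean_jaccard": jmean,
                "sd_jaccard": jsd,
                "stability_score": phi,
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("method")

    comparisons = []
    for a, b in combinations(methods, 2):
        t_unpaired = stats.ttest_ind(jac_values[a], jac_values[b], equal_var=False)
        t_paired = stats.ttest_rel(jac_values[a], jac_values[b])
        try:
            zstat, zp = nogueira_test(result_sets[a], result_sets[b])
        except ValueError:
            zstat, zp = np.nan, np.nan
        comparisons.append(
            {
                "method_a": a,
                "method_b": b,
                "jac_t_p": float(t_unpaired.pvalue),
                "jac_paired_t_p": float(t_paired.pvalue),
                "stability_z": zstat,
                "stability_p": zp,
            }
        )
    return {
        "run_sets": result_sets,
        "summary": summary,
        "comparisons": pd.DataFrame(comparisons),
        "jaccard_values": jac_values,
    }
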