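"""Preliminary feature filtering: variance, repeatability (ICC) and
univariate-association gates.

A feature survives iff it is non-constant, agrees across the two replicate
delineations (ICC >= 0.9 with a significant F-test by default), and
discriminates the two classes univariately (t-test or Mann-Whitney U,
chosen by a per-class Shapiro-Wilk normality gate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import FeatureTable, ReplicatePair

__all__ = [
    "PrefilterConfig",
    "variance_filter",
    "icc_agreement",
    "univariate_test",
    "run_prefilter",
    "passing_features",
]


@dataclass
class PrefilterConfig:
    icc_min: float = 0.9
    icc_p_max: float = 0.05
    univariate_p_max: float = 0.05
    normality_alpha: float = 0.05
    variance_min: float = 0.0
    icc_form: str = "agreement"  # or "consistency"

    def __post_init__(self) -> None:
        for name in ("icc_min", "icc_p_max", "univariate_p_max", "normality_alpha", "variance_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.icc_form not in ("agreement", "consistency"):
            raise ValueError("icc_form must be 'agreement' or 'consistency'")


def variance_filter(table: FeatureTable, variance_min: float = 0.0) -> set[str]:
    """Feature IDs whose sample variance (ddof=1) exceeds ``variance_min``."""
    var = table.values.var(axis=0, ddof=1)
    return {f for f, v in zip(table.feature_ids, var) if v > variance_min}


def icc_agreement(x: np.ndarray, y: np.ndarray, form: str = "agreement") -> tuple[float, float]:
    """Single-measurement two-way mixed-effects ICC between paired measurements.

    ``form='agreement'`` gives absolute agreement (ICC(A,1), computationally
    the two-way random-effects ICC(2,1)); ``form='consistency'`` gives
    ICC(C,1) / ICC(3,1).  The p-value is from the F-test of zero
    subject-to-subject reliability, F = MSR/MSE with (n-1, (n-1)(k-1)) df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in ICC input")
    data = np.column_stack([x, y])  # n subjects x k=2 raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    if ss_total <= 0:
        raise ValueError("zero total variance: uninformative feature; run variance_filter first")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "agreement":
        icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    else:
        icc = (msr - mse) / (msr + (k - 1) * mse)
    if mse <= 0:  # perfect agreement: F-test degenerates, p -> 0
        return float(icc), 0.0
    f = msr / mse
    p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def univariate_test(
    values: np.ndarray, labels: np.ndarray, normality_alpha: float = 0.05
) -> tuple[float, str]:
    """Two-class univariate association p-value.

    Uses Student's t-test when a Shapiro-Wilk test accepts normality in both
    classes at ``normality_alpha``, otherwise the Mann-Whitney U test with
    normal approximation and tie correction.  Returns ``(p, test_used)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    g0 = values[labels == 0]
    g1 = values[labels == 1]
    if g0.size < 3 or g1.size < 3:
        raise ValueError("both classes must be present with >= 3 samples")
    normal = True
    for g in (g0, g1):
        if np.ptp(g) == 0:  # Shapiro undefined on constant data; not normal
            normal = False
            break
        if stats.shapiro(g).pvalue <= normality_alpha:
            normal = False
            break
    if normal:
        p = stats.ttest_ind(g0, g1, equal_var=True).pvalue
        return float(p), "t"
    p = stats.mannwhitneyu(g0, g1, alternative="two-sided", method="asymptotic").pvalue
    return float(min(p, 1.0)), "mann-whitney"


def run_prefilter(
    pair: ReplicatePair,
    labels: np.ndarray | None = None,
    config: PrefilterConfig | None = None,
) -> pd.DataFrame:
    """Apply all three gates; one row per feature.

    Columns: ``variance_pass``, ``icc``, ``icc_p``, ``icc_pass``,
    ``test_used``, ``univariate_p``, ``univariate_pass``, ``overall_pass``.
    ``overall_pass`` is a pure conjunction of the three gates (order-free).
    ICC/univariate statistics are still reported for variance-failing
    features where computable (NaN otherwise).
    """
    config = config or PrefilterConfig()
    table = pair.primary
    if labels is None:
        labels = table.labels
    if labels is None:
        raise ValueError("labels required for the univariate gate")
    labels = np.asarray(labels)
    var_pass = variance_filter(table, config.variance_min)
    rows = []
    for j, fid in enumerate(table.feature_ids):
        v_ok = fid in var_pass
        icc = icc_p = uni_p = np.nan
        test_used = ""
        if v_ok:
            icc, icc_p = icc_agreement(
                table.values[:, j], pair.replicate.values[:, j], config.icc_form
            )
            uni_p, test_used = univariate_test(
                table.values[:, j], labels, config.normality_alpha
            )
        icc_ok = v_ok and icc >= config.icc_min and icc_p <= config.icc_p_max
        uni_ok = v_ok and uni_p <= config.univariate_p_max
        rows.append(
            {
                "feature_id": fid,
                "variance_pass": v_ok,
                "icc": icc,
                "icc_p": icc_p,
                "icc_pass": icc_ok,
                "test_used": test_used,
                "univariate_p": uni_p,
                "univariate_pass": uni_ok,
                "overall_pass": v_ok and icc_ok and uni_ok,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def passing_features(report: pd.DataFrame) -> list[str]:
    """Feature IDs with ``overall_pass`` set, in table order."""
    return list(report.index[report["overall_pass"]])
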