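"""Packaged final five-fold ensemble model (published coefficient table).

Seventeen distinct radiomic features carry a coefficient in at least one of
the five fold-level linear support-vector-regression models.  Per-fold Youden
thresholds are recovered from the published ensemble weights via
``threshold_i = 1 / (5 * weight_i)``.

The original standardization constants are not published, so the fixture
carries placeholder Z-score parameters (mean 0, sd 1); scores on real data
are therefore not reproducible, only the model structure and arithmetic.
"""

from __future__ import annotations

import numpy as np

from .data_model import EnsembleModel, LinearModelRecord, ZScoreParams

__all__ = ["FINAL_ENSEMBLE_WEIGHTS", "FINAL_ENSEMBLE_INTERCEPTS", "load_final_ensemble"]

# rows: (imaging filter, feature class, feature name, coef per fold; None = absent)
_COEF_TABLE = [
    ("original", "shape", "SurfaceVolumeRatio",
     (-0.34350, -0.41914, -0.35446, -0.41196, -0.35104)),
    ("lbp-3D-k", "glrlm", "LongRunHighGrayLevelEmphasis",
     (-0.23201, -0.23496, -0.19496, -0.23516, -0.18680)),
    ("original", "shape", "SurfaceArea",
     (-0.15209, -0.12242, -0.13933, -0.05791, -0.10701)),
    ("lbp-3D-m2", "first-order", "Kurtosis",
     (-0.07727, -0.16856, -0.15919, -0.17252, None)),
    ("log-sigma-0-4492-mm-3D", "first-order", "Mean",
     (0.08879, None, 0.05899, -0.06722, 0.15951)),
    ("original", "shape", "LeastAxisLength",
     (0.10404, 0.11893, 0.10616, None, None)),
    ("exponential", "glcm", "SumEntropy",
     (0.04001, None, None, -0.00654, 0.13320)),
    ("lbp-3D-m1", "first-order", "Kurtosis",
     (-0.08219, None, None, None, -0.14464)),
    ("gradient", "first-order", "Energy",
     (0.05771, 0.01792, None, None, None)),
    ("lbp-2D", "glcm", "DifferenceVariance",
     (-0.02907, None, None, None, None)),
    ("exponential", "first-order", "Energy",
     (None, -0.05008, None, None, 0.02571)),
    ("exponential", "first-order", "Variance",
     (None, None, None, None, -0.12470)),
    ("exponential", "glrlm", "RunVariance",
     (None, -0.04025, None, None, None)),
    ("lbp-3D-m1", "glcm", "ClusterShade",
     (None, None, -0.06451, None, None)),
    ("lbp-3D-m2", "glrlm", "ShortRunHighGrayLevelEmphasis",
     (None, 0.00498, None, None, None)),
    ("log-sigma-0-4492-mm-3D", "first-order", "RobustMeanAbsoluteDeviation",
     (None, None, None, -0.10530, None)),
    ("original", "glrlm", "RunEntropy",
     (None, None, None, None, 0.05171)),
]

FINAL_ENSEMBLE_INTERCEPTS = (0.48176, 0.49719, 0.49814, 0.47659, 0.47752)
FINAL_ENSEMBLE_WEIGHTS = (0.33508, 0.36677, 0.62281, 0.42553, 0.33341)


def load_final_ensemble() -> EnsembleModel:
    """Build the published five-fold linear ensemble as an :class:`EnsembleModel`."""
    models = []
    for fold in range(5):
        feats, coefs = [], []
        for filt, fclass, fname, per_fold in _COEF_TABLE:
            c = per_fold[fold]
            if c is not None:
                feats.append(f"{filt}|{fclass}|{fname}")
                coefs.append(c)
        threshold = 1.0 / (5.0 * FINAL_ENSEMBLE_WEIGHTS[fold])
        models.append(
            LinearModelRecord(
                feats,
                np.asarray(coefs),
                FINAL_ENSEMBLE_INTERCEPTS[fold],
                threshold,
                ZScoreParams(np.zeros(len(feats)), np.ones(len(feats))),
            )
        )
    return EnsembleModel(
        models,
        np.asarray(FINAL_ENSEMBLE_WEIGHTS),
        decision_threshold=1.0,
        provenance="published five-fold SVR ensemble (placeholder z-score params)",
    )
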