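"""Elastic-net penalized logistic regression solver.

Implements FISTA (accelerated proximal gradient) on the objective

    f(w, b) = sum_i c_i * log(1 + exp(-t_i * (x_i . w + b)))
              + lam * (l1_ratio * ||w||_1 + (1 - l1_ratio)/2 * ||w||_2^2)

with t_i in {-1, +1} and c_i the per-sample weights normalized to sum to 1
(so `lam` is on the mean-loss scale regardless of n).  The intercept is
unpenalized.  The proximal step yields exact zeros, which downstream
selection criteria rely on.

A numba-jitted kernel is used when numba is importable; a pure-numpy
implementation with identical semantics is the fallback.
"""

from __future__ import annotations

import numpy as np

__all__ = ["enet_logistic", "enet_objective"]


def _kernel_py(X, t, c, lam, l1_ratio, max_iter, tol):
    n, d = X.shape
    w = np.zeros(d)
    b = 0.0
    l1 = lam * l1_ratio
    l2 = lam * (1.0 - l1_ratio)

    # Lipschitz bound for the smooth part: 0.25 * lambda_max(Xa^T diag(c) Xa) + l2
    # (Xa = X with an appended 1s column for the intercept), via power iteration.
    sc = np.sqrt(c)
    Xa = np.empty((n, d + 1))
    for i in range(n):
        for j in range(d):
            Xa[i, j] = X[i, j] * sc[i]
        Xa[i, d] = sc[i]
    v = np.ones(d + 1) / np.sqrt(d + 1.0)
    s = 0.0
    for _ in range(30):
        u = Xa.T @ (Xa @ v)
        s = np.sqrt(u @ u)
        if s <= 0.0:
            break
        v = u / s
    L = 0.25 * s + l2 + 1e-12
    step = 1.0 / L

    zw = w.copy()
    zb = b
    theta = 1.0
    obj_prev = np.inf
    for it in range(max_iter):
        m = t * (X @ zw + zb)
        # d/dm of c*log(1+exp(-m)) = -c*t*sigmoid(-m)
        g = -c * t / (1.0 + np.exp(m))
        gw = X.T @ g + l2 * zw
        gb = g.sum()
        w_new = zw - step * gw
        # soft threshold
        thr = step * l1
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - thr, 0.0)
        b_new = zb - step * gb

        theta_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * theta * theta))
        mom = (theta - 1.0) / theta_new
        zw = w_new + mom * (w_new - w)
        zb = b_new + mom * (b_new - b)
        w, b, theta = w_new, b_new, theta_new

        if it % 10 == 9:
            m = t * (X @ w + b)
            obj = float(np.sum(c * np.log1p(np.exp(-m)))) + l1 * float(
                np.abs(w).sum()
            ) + 0.5 * l2 * float(w @ w)
            if abs(obj_prev - obj) <= tol * max(1.0, abs(obj)):
                return w, b, True
            obj_prev = obj
    return w, b, False


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _kernel_nb = njit(cache=True, fastmath=False)(_kernel_py)
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _kernel_nb = None
    _HAVE_NUMBA = False


def enet_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    l1_ratio: float,
    sample_weight: np.ndarray | None = None,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, bool]:
    """Fit elastic-net logistic regression; return (coef, intercept, converged).

    ``y`` must be 0/1.  ``sample_weight`` is normalized internally to sum 1.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    if sample_weight is None:
        c = np.full(n, 1.0 / n)
    else:
        sample_weight = np.asarray(sample_weight, dtype=np.float64)
        tot = sample_weight.sum()
        if tot <= 0:
            raise ValueError("sample weights must have positive sum")
        c = sample_weight / tot
    t = 2.0 * y - 1.0
    kern = _kernel_nb if _HAVE_NUMBA else _kernel_py
    w, b, ok = kern(X, t, c, float(lam), float(l1_ratio), int(max_iter), float(tol))
    return w, float(b), bool(ok)


def enet_objective(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    b: float,
    lam: float,
    l1_ratio: float,
    sample_weight: np.ndarray | None = None,
) -> float:
    """Value of the penalized mean logistic loss at (w, b)."""
    n = X.shape[0]
    c = np.full(n, 1.0 / n) if sample_weight is None else (
        np.asarray(sample_weight, float) / np.sum(sample_weight)
    )
    t = 2.0 * np.asarray(y, float) - 1.0
    m = t * (X @ w + b)
    # numerically safe log(1+exp(-m))
    loss = np.sum(c * (np.logaddexp(0.0, -m)))
    pen = lam * (l1_ratio * np.abs(w).sum() + 0.5 * (1.0 - l1_ratio) * (w @ w))
    return float(loss + pen)
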