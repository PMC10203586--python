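"""Cyclic coordinate-descent kernel for the elastic-net objective

    (1/2n) ||y - X b||^2 + lambda1 ||b||_1 + (lambda2/2) ||b||^2

on pre-standardised predictors. Compiled with numba when available; the
pure-NumPy fallback is identical and used automatically otherwise.
"""

from __future__ import annotations

import numpy as np


def _cd_loop(X, y, b, lambda1, lambda2, col_scale, tol, max_iter):
    n, p = X.shape
    r = y - X @ b
    it = 0
    for it in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            bj = b[j]
            rho = col_scale[j] * bj
            for i in range(n):
                rho += X[i, j] * r[i] / n
            # soft threshold
            if rho > lambda1:
                bn = (rho - lambda1) / (col_scale[j] + lambda2)
            elif rho < -lambda1:
                bn = (rho + lambda1) / (col_scale[j] + lambda2)
            else:
                bn = 0.0
            d = bn - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * d
                b[j] = bn
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if max_delta < tol:
            return it, True
    return it, False


try:  # pragma: no cover - exercised whenever numba is installed
    from numba import njit

    _cd_loop = njit(cache=True, fastmath=False)(_cd_loop)
except ImportError:  # pragma: no cover
    pass


def cd_solve(X, y, lambda1, lambda2, b0=None, tol=1e-7, max_iter=10000):
    """Solve the elastic-net problem; returns (b, n_iter, converged)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    b = np.zeros(p) if b0 is None else np.asarray(b0, dtype=np.float64).copy()
    col_scale = (X**2).sum(axis=0) / n
    it, conv = _cd_loop(X, y, b, float(lambda1), float(lambda2), col_scale,
                        float(tol), int(max_iter))
    return b, it, conv
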