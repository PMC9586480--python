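"""Locally weighted polynomial regression (LOESS).

Local degree-2 fits with tricube weights over a span given as the fraction of
points entering each local fit, i.e. the classic smoother of Cleveland as
implemented by R's ``loess`` with ``degree = 2``.  Implemented here because
``statsmodels.lowess`` only offers local degree 1.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError

__all__ = ["loess_smooth"]


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.75,
                 degree: int = 2, x_eval: np.ndarray | None = None) -> np.ndarray:
    """Smooth ``y(x)`` and return fitted values at ``x_eval`` (default ``x``).

    Parameters
    ----------
    x, y : 1-D arrays of equal length, ``x`` need not be sorted.
    span : fraction of the points used in each local fit, ``0 < span <= 1``.
    degree : local polynomial degree (2 unless stated otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise DataError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 10:
        raise DataError(f"need at least 10 points for LOESS, got {n}")
    if not 0 < span <= 1:
        raise DataError(f"span must be in (0, 1], got {span}")
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)
    if k < degree + 1:
        raise DataError("span selects fewer points than the local polynomial needs")

    xe = x if x_eval is None else np.asarray(x_eval, dtype=float)
    out = np.empty(xe.size)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for i, x0 in enumerate(xe):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        if h == 0:  # all selected points coincide with x0
            out[i] = ys[idx].mean()
            continue
        w = (1 - (d[idx] / h) ** 3) ** 3
        w = np.clip(w, 0, None)
        t = xs[idx] - x0  # centre for conditioning
        design = np.vander(t, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], ys[idx] * sw, rcond=None)
        out[i] = coef[0]
    return out
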