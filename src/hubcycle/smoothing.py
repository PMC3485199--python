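"""Locally weighted polynomial regression (loess) for expression time courses.

Each gene's series is smoothed independently with tricube-weighted local
polynomial fits over the span-nearest non-missing neighbours, evaluated at
the observed timepoints only (synchronized-culture data are rendered at
sample points; no interpolation grid). The default is span 0.5, local
quadratic (degree 2), zero robustness iterations — the defaults of the
classical loess smoother; output matches R's
``loess(span=0.5, degree=2, surface="direct")`` to ~1e-10. Local linear
(degree 1) is supported but attenuates cell-cycle-scale oscillations far
more strongly on sparse grids (see docs/methods.md).

Missing values are excluded from the local fits, never interpolated first,
and remain missing in the output.
"""

from __future__ import annotations

import math

import numpy as np

from .types import ExpressionMatrix, SmoothedMatrix

__all__ = ["smooth_series", "smooth_matrix", "MIN_POINTS"]

#: minimum non-missing points for a gene to be smoothable
MIN_POINTS = 4


def _can_smooth(n_usable: int, span: float) -> bool:
    return n_usable >= MIN_POINTS and span * n_usable >= 2.0


def smooth_series(
    times: np.ndarray,
    values: np.ndarray,
    missing: np.ndarray | None = None,
    span: float = 0.5,
    degree: int = 2,
) -> np.ndarray:
    """Smooth one series; returns the smoothed values at the observed times.

    Positions missing in the input are NaN in the output. If fewer than
    :data:`MIN_POINTS` usable points exist (or the span window would hold
    fewer than two), the series is unsmoothable and an all-NaN array is
    returned — callers flag the gene rather than raising, so it propagates
    to *unclassifiable* downstream.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = ~np.isfinite(values)
    missing = np.asarray(missing, dtype=bool)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")

    out = np.full(times.shape, np.nan)
    usable = ~missing
    t_u = times[usable]
    y_u = values[usable]
    n_u = t_u.size
    if not _can_smooth(n_u, span):
        return out

    q = max(int(math.ceil(span * n_u)), degree + 1, 2)
    q = min(q, n_u)
    for i in np.flatnonzero(usable):
        t0 = times[i]
        d = np.abs(t_u - t0)
        # span-nearest neighbours; distance ties broken toward earlier time
        order = np.lexsort((t_u, d))
        sel = order[:q]
        h = d[sel].max()
        if h == 0.0:
            out[i] = y_u[sel].mean()
            continue
        w = (1.0 - (d[sel] / h) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        pos = w > 0
        distinct = np.unique(t_u[sel][pos]).size
        deg = min(degree, distinct - 1)
        if deg < 1:
            out[i] = float(np.average(y_u[sel], weights=w)) if w.sum() > 0 else y_u[sel].mean()
            continue
        dt = t_u[sel] - t0
        X = np.column_stack([dt**k for k in range(deg + 1)])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y_u[sel] * sw, rcond=None)
        out[i] = beta[0]
    return out


def smooth_matrix(
    matrix: ExpressionMatrix, span: float = 0.5, degree: int = 2
) -> SmoothedMatrix:
    """Apply :func:`smooth_series` row-wise.

    Genes with too few usable points become all-missing rows and are listed
    in ``unsmoothable``.
    """
    values = np.zeros_like(matrix.values)
    miss = matrix.missing.copy()
    unsmoothable: list[str] = []
    for i, gene in enumerate(matrix.genes):
        sm = smooth_series(
            matrix.times, matrix.values[i], matrix.missing[i], span=span, degree=degree
        )
        ok = np.isfinite(sm)
        if not ok.any():
            unsmoothable.append(gene)
            miss[i, :] = True
            continue
        values[i, ok] = sm[ok]
        miss[i, ~ok] = True
    return SmoothedMatrix(
        experiment_id=matrix.experiment_id,
        genes=list(matrix.genes),
        times=matrix.times.copy(),
        values=values,
        missing=miss,
        span=span,
        degree=degree,
        unsmoothable=frozenset(unsmoothable),
    )
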