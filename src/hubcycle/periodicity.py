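"""Periodicity calls for smoothed cell-cycle expression series.

The published analysis judged periodic vs non-periodic expression by eye
(validated against cell-cycle databases). This module replaces that visual
judgement with an explicit, testable statistic: a least-squares cosinor fit

    x(t) ~ m + A * cos(2*pi*(t - phi) / T)

at a period ``T`` shared by all genes of a synchronization experiment
(synchronized cultures oscillate together, so ``T`` is estimated once per
experiment, not per gene), plus a permutation test that shuffles timepoint
labels to ask whether the fraction of variance the cosine captures is
surprising. A gene is called *periodic* when the permutation p-value clears
``alpha`` and the fitted amplitude clears a floor (default 0.2 log2 units —
oscillations smaller than that sit inside array noise and below the
rendering threshold scale). Calls are combined across experiments by strict
majority; ties or fewer than two usable experiments yield *unclassifiable*,
mirroring hubs whose expression was inconsistent between synchronization
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import SmoothedMatrix

__all__ = [
    "PeriodicityScore",
    "cosinor_fit",
    "estimate_period",
    "score_gene",
    "call_gene",
    "combine_calls",
    "DEFAULT_PERIOD_GRID",
]

#: candidate cell-cycle periods, minutes
DEFAULT_PERIOD_GRID = tuple(float(t) for t in range(40, 102, 2))

#: minimum usable points for a per-gene score
MIN_USABLE = 6
#: minimum usable points for a gene to inform the period estimate
MIN_USABLE_PERIOD = 8


@dataclass(frozen=True)
class PeriodicityScore:
    """Cosinor fit summary for one gene in one experiment.

    ``phase_phi`` is the peak time in minutes, in ``[0, period_T)``.
    ``p_perm`` is the permutation p-value ``(1 + #{r2_perm >= r2}) /
    (1 + n_perm)``. ``usable`` is False when the series has too few points,
    does not span a full period, or was unsmoothable.
    """

    gene: str
    experiment_id: str
    period_T: float
    amplitude_A: float
    phase_phi: float
    r_squared: float
    p_perm: float
    n_usable: int
    usable: bool
    seed: object = None

    def __post_init__(self) -> None:
        if self.usable:
            if self.amplitude_A < 0:
                raise ValueError("amplitude must be non-negative")
            if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
                raise ValueError("r_squared out of [0, 1]")
            if not (0.0 < self.p_perm <= 1.0):
                raise ValueError("p_perm out of (0, 1]")
            if not (0.0 <= self.phase_phi < self.period_T):
                raise ValueError("phase out of [0, T)")


def _design(t: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi * t / period
    return np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])


def cosinor_fit(
    times: np.ndarray, values: np.ndarray, period: float
) -> tuple[float, float, float, float]:
    """Least-squares cosinor at fixed period.

    Returns ``(mesor, amplitude, phase, r_squared)`` with the phase the peak
    time in minutes in ``[0, period)``. A zero-variance series returns
    amplitude 0 and r-squared 0.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.ptp(y) == 0.0:
        return float(y[0]) if y.size else 0.0, 0.0, 0.0, 0.0
    X = _design(t, period)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, a, b = beta
    amp = float(np.hypot(a, b))
    phase = float((period / (2.0 * np.pi)) * np.arctan2(b, a) % period)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0.0:
        return float(m), 0.0, 0.0, 0.0
    resid = y - X @ beta
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(m), amp, phase, min(max(r2, 0.0), 1.0)


def estimate_period(
    matrix: SmoothedMatrix, grid: Sequence[float] = DEFAULT_PERIOD_GRID
) -> float:
    """Estimate the shared cell-cycle period of one experiment.

    Over the candidate grid, returns the period maximizing the mean cosinor
    r-squared across usable genes (>= 8 non-missing points, non-zero
    variance). Ties break toward the shorter period.
    """
    grid = sorted(float(p) for p in grid)
    if not grid:
        raise ValueError("empty period grid")
    rows = []
    for i in range(matrix.n_genes):
        ok = ~matrix.missing[i]
        if ok.sum() < MIN_USABLE_PERIOD:
            continue
        y = matrix.values[i, ok]
        if np.ptp(y) == 0.0:
            continue
        rows.append((matrix.times[ok], y))
    if not rows:
        raise ValueError("no usable genes for period estimation")
    mean_r2 = np.empty(len(grid))
    for k, period in enumerate(grid):
        mean_r2[k] = np.mean([cosinor_fit(t, y, period)[3] for t, y in rows])
    return grid[int(np.argmax(mean_r2))]  # argmax takes first max: shorter period


def _unusable(gene, experiment_id, period, n_usable, seed) -> PeriodicityScore:
    return PeriodicityScore(
        gene=gene,
        experiment_id=experiment_id,
        period_T=period,
        amplitude_A=0.0,
        phase_phi=0.0,
        r_squared=0.0,
        p_perm=1.0,
        n_usable=n_usable,
        usable=False,
        seed=seed,
    )


def score_gene(
    times: np.ndarray,
    values: np.ndarray,
    period_T: float,
    missing: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: object = 0,
    gene: str = "",
    experiment_id: str = "",
) -> PeriodicityScore:
    """Cosinor fit plus timepoint-shuffle permutation test at fixed period.

    The series must have at least :data:`MIN_USABLE` usable points and span
    at least one full period within the sampled window, otherwise the result
    is marked unusable (never an exception). The permutation stream is drawn
    from ``numpy.random.default_rng(seed)``; the seed is recorded in the
    score for reproducibility.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if missing is None:
        missing = ~np.isfinite(y)
    ok = ~np.asarray(missing, dtype=bool)
    n_usable = int(ok.sum())
    if n_usable < MIN_USABLE or (t[ok].max() - t[ok].min()) < period_T:
        return _unusable(gene, experiment_id, period_T, n_usable, seed)
    t, y = t[ok], y[ok]
    mesor, amp, phase, r2 = cosinor_fit(t, y, period_T)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if np.ptp(y) == 0.0 or ss_tot <= 0.0:
        # constant series: cosine explains nothing, amplitude 0
        return PeriodicityScore(
            gene=gene, experiment_id=experiment_id, period_T=period_T,
            amplitude_A=0.0, phase_phi=0.0, r_squared=0.0, p_perm=1.0,
            n_usable=n_usable, usable=True, seed=seed,
        )
    X = _design(t, period_T)
    Q, _ = np.linalg.qr(X)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, t.size), dtype=float)
    for k in range(n_perm):
        perms[k] = y[rng.permutation(t.size)]
    # r2 = (||Q^T y||^2 - n*mean^2) / ss_tot ; mean and ||y|| are permutation-invariant
    proj = perms @ Q
    ss_mean = t.size * y.mean() ** 2
    r2_perm = ((proj**2).sum(axis=1) - ss_mean) / ss_tot
    r2_obs = (float(((Q.T @ y) ** 2).sum()) - ss_mean) / ss_tot
    p = (1.0 + int(np.sum(r2_perm >= r2_obs))) / (1.0 + n_perm)
    return PeriodicityScore(
        gene=gene,
        experiment_id=experiment_id,
        period_T=period_T,
        amplitude_A=amp,
        phase_phi=phase,
        r_squared=r2,
        p_perm=p,
        n_usable=n_usable,
        usable=True,
        seed=seed,
    )


def call_gene(
    score: PeriodicityScore, alpha: float = 0.05, min_amplitude: float = 0.2
) -> str:
    """Per-experiment verdict: ``periodic`` / ``aperiodic`` / ``unusable``.

    Periodic requires both a significant permutation p-value and a fitted
    amplitude at or above the floor; a significant but tiny oscillation is
    still called aperiodic.
    """
    if not score.usable:
        return "unusable"
    if score.p_perm <= alpha and score.amplitude_A >= min_amplitude:
        return "periodic"
    return "aperiodic"


def combine_calls(calls: Iterable[str] | Mapping[str, str]) -> str:
    """Combine per-experiment calls into ``periodic`` / ``aperiodic`` /
    ``unclassifiable``.

    Strict majority among usable experiments wins; a tie, or fewer than two
    usable experiments, is unclassifiable (expression inconsistent between
    synchronization conditions, or insufficient data).
    """
    if isinstance(calls, Mapping):
        calls = list(calls.values())
    else:
        calls = list(calls)
    if not calls:
        raise ValueError("no experiments")
    for c in calls:
        if c not in ("periodic", "aperiodic", "unusable"):
            raise ValueError(f"bad call: {c!r}")
    usable = [c for c in calls if c != "unusable"]
    if len(usable) < 2:
        return "unclassifiable"
    n_p = usable.count("periodic")
    n_a = usable.count("aperiodic")
    if n_p > n_a:
        return "periodic"
    if n_a > n_p:
        return "aperiodic"
    return "unclassifiable"
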