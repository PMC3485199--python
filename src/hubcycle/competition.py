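"""Interface-competition metrics for singlish hubs.

A hub with one or two interaction interfaces can physically engage at most
one or two partners at once. When more partners are simultaneously
expressed (active under the rendering threshold) than the hub has
interfaces, those partners are in potential competition. This module counts
simultaneously active direct partners over the sampled time course, the
excess over the interface count, and pairwise overlap (Jaccard index of
active-time sets) between partners — low mean overlap is the "staggered
expression peaks" regime that reduces competition at a static hub.

All partners are treated as competing for all interfaces: which partner
binds through which interface is generally unknown, so per-interface
assignment is out of scope (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .temporal import ActivityMask
from .types import normalize_gene

__all__ = [
    "CompetitionProfile",
    "OverlapMatrix",
    "competition_profile",
    "partner_overlap",
    "flag_staggered",
    "DEFAULT_STAGGERED_CUTOFF",
]

DEFAULT_STAGGERED_CUTOFF = 0.5


@dataclass(frozen=True)
class CompetitionProfile:
    """Per-time competition summary for one hub.

    ``active_partner_count[t]`` counts direct partners active at sampled
    time t irrespective of the hub's own activity; the hub's activity is
    reported separately (``hub_active``) and the *realized* summary
    restricts to hub-active times, since partners can only compete for an
    interface that is present.
    """

    hub: str
    times: np.ndarray
    partners: tuple[str, ...]
    n_interfaces: int
    active_partner_count: np.ndarray
    excess: np.ndarray
    max_simultaneous: int
    fraction_time_competitive: float
    hub_active: np.ndarray
    fraction_time_competitive_hub_active: float

    def __post_init__(self) -> None:
        if self.n_interfaces not in (1, 2):
            raise ValueError("n_interfaces must be 1 or 2")
        if np.any(self.active_partner_count < 0) or np.any(
            self.active_partner_count > len(self.partners)
        ):
            raise ValueError("active partner count out of range")
        expect = np.maximum(0, self.active_partner_count - self.n_interfaces)
        if not np.array_equal(expect, self.excess):
            raise ValueError("excess inconsistent with count and interfaces")


def competition_profile(
    hub: str,
    network: nx.Graph,
    mask: ActivityMask,
    n_interfaces: int,
) -> CompetitionProfile:
    """Count simultaneously active 1-step partners of ``hub`` over time."""
    hub = normalize_gene(hub)
    if hub not in network:
        raise KeyError(f"hub not in network: {hub}")
    partners = tuple(sorted(network.neighbors(hub)))
    n_t = mask.times.size
    count = np.zeros(n_t, dtype=int)
    for p in partners:
        for j in mask.active_times(p):
            count[j] += 1
    excess = np.maximum(0, count - n_interfaces)
    hub_active = np.zeros(n_t, dtype=bool)
    for j in mask.active_times(hub):
        hub_active[j] = True
    frac = float(np.mean(excess > 0)) if n_t else 0.0
    if hub_active.any():
        frac_hub = float(np.mean(excess[hub_active] > 0))
    else:
        frac_hub = 0.0
    return CompetitionProfile(
        hub=hub,
        times=mask.times.copy(),
        partners=partners,
        n_interfaces=n_interfaces,
        active_partner_count=count,
        excess=excess,
        max_simultaneous=int(count.max()) if n_t else 0,
        fraction_time_competitive=frac,
        hub_active=hub_active,
        fraction_time_competitive_hub_active=frac_hub,
    )


@dataclass(frozen=True)
class OverlapMatrix:
    """Pairwise Jaccard overlap of partner active-time sets.

    ``staggered_score`` is the mean off-diagonal Jaccard; pairs where both
    partners are never active get Jaccard 0 and are flagged in
    ``both_empty_pairs``.
    """

    partners: tuple[str, ...]
    jaccard: np.ndarray
    staggered_score: float
    both_empty_pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def pair(self, a: str, b: str) -> float:
        ia = self.partners.index(normalize_gene(a))
        ib = self.partners.index(normalize_gene(b))
        return float(self.jaccard[ia, ib])


def partner_overlap(mask: ActivityMask, partners) -> OverlapMatrix:
    """Jaccard index of active-time index sets for every partner pair."""
    partners = tuple(sorted(normalize_gene(p) for p in partners))
    if len(partners) < 2:
        raise ValueError("need at least 2 partners")
    sets = {p: mask.active_times(p) for p in partners}
    n = len(partners)
    J = np.zeros((n, n))
    empty_pairs = set()
    for i, p in enumerate(partners):
        J[i, i] = 1.0 if sets[p] else 0.0
    for (i, a), (j, b) in combinations(enumerate(partners), 2):
        union = sets[a] | sets[b]
        if not union:
            J[i, j] = J[j, i] = 0.0
            empty_pairs.add((a, b))
            continue
        J[i, j] = J[j, i] = len(sets[a] & sets[b]) / len(union)
    off = [J[i, j] for i, j in combinations(range(n), 2)]
    return OverlapMatrix(
        partners=partners,
        jaccard=J,
        staggered_score=float(np.mean(off)),
        both_empty_pairs=frozenset(empty_pairs),
    )


def flag_staggered(
    overlap: OverlapMatrix, cutoff: float = DEFAULT_STAGGERED_CUTOFF
) -> bool:
    """True when partners are expressed at mostly non-overlapping times."""
    return overlap.staggered_score < cutoff
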