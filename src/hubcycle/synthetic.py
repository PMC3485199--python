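"""Synthetic synchronized-culture expression data and hub networks with
ground truth.

The generator emulates the statistical structure the analysis assumes:

* periodic genes: ``x(t) = m + A*cos(2*pi*(t - phi)/T) + eps``,
  ``eps ~ N(0, noise_sd^2)``, with a shared period per cohort (synchronized
  cultures) and gene-specific amplitude and phase;
* static genes: ``x(t) = m + eps``;
* stochastic genes: a stationary AR(1) series (``rho`` 0.6, innovation sd
  ``noise_sd``), drawn independently per experiment, so their apparent
  behaviour is inconsistent between synchronization conditions — the path
  by which real noisy hubs end up unclassified;
* networks: each hub gets its own dedicated partners (hub-and-spoke),
  background genes attach sparsely so the graph stays connected, plus
  random background cross-links.

Defaults mirror the classical synchronization designs: three experiments
sampled 18 points/119 min, 24/290 and 17/160, a 66-minute cell-cycle
period, log2-ratio amplitudes 0.4-1.0, noise sd 0.15, baselines near 0 so
the -0.2 rendering threshold is meaningful, and 100 genes in total.

Everything is driven by one integer seed through ``numpy.random.default_rng``;
reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import networkx as nx
import numpy as np

from .types import ExpressionMatrix

__all__ = [
    "HubSpec",
    "SimulationConfig",
    "GroundTruth",
    "HubTruth",
    "simulate_network",
    "simulate_expression",
    "simulate_cohort",
    "make_staggered_partners",
]

HubKind = Literal[
    "dynamic_competitive", "static_noncompetitive", "coordinate", "stochastic"
]

#: intended (table class, regulatory class) per hub kind
_HUB_TRUTH = {
    "dynamic_competitive": ("Dynamic", "competitive"),
    "static_noncompetitive": ("Static", "non_competitive"),
    "coordinate": ("Dynamic", "none"),
    "stochastic": ("unassigned", "none"),
}


@dataclass(frozen=True)
class HubSpec:
    n_interfaces: int
    n_partners: int
    kind: HubKind

    def __post_init__(self) -> None:
        if self.n_interfaces not in (1, 2):
            raise ValueError("n_interfaces must be 1 or 2")
        if self.n_partners < 1:
            raise ValueError("a hub needs at least one partner")
        if self.kind not in _HUB_TRUTH:
            raise ValueError(f"unknown hub kind: {self.kind!r}")


def _default_hub_specs() -> tuple[HubSpec, ...]:
    return (
        HubSpec(2, 5, "dynamic_competitive"),
        HubSpec(1, 5, "dynamic_competitive"),
        HubSpec(2, 5, "dynamic_competitive"),
        HubSpec(1, 5, "static_noncompetitive"),
        HubSpec(2, 5, "static_noncompetitive"),
        HubSpec(1, 5, "static_noncompetitive"),
        HubSpec(1, 4, "coordinate"),
        HubSpec(2, 4, "coordinate"),
        HubSpec(2, 4, "stochastic"),
        HubSpec(1, 4, "stochastic"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic cohort.

    ``experiments`` is a list of ``(duration_minutes, n_points)`` sampling
    grids, one per synchronization experiment. The default cohort has 10
    hubs (3 competitive, 3 non-competitive, 2 co-ordinately regulated, 2
    stochastic), their 46 dedicated partners and 44 background genes — 100
    genes in all.
    """

    seed: int = 7
    experiments: tuple[tuple[float, int], ...] = ((119.0, 18), (290.0, 24), (160.0, 17))
    period_T: float = 66.0
    amplitude_range: tuple[float, float] = (0.4, 1.0)
    noise_sd: float = 0.15
    baseline_range: tuple[float, float] = (-0.05, 0.05)
    n_background_genes: int = 44
    hub_specs: tuple[HubSpec, ...] = field(default_factory=_default_hub_specs)
    cross_link_prob: float = 0.02
    stochastic_rho: float = 0.6
    background_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)  # periodic/static/stochastic

    def __post_init__(self) -> None:
        if not self.hub_specs:
            raise ValueError("hub_specs must be non-empty")
        for dur, n in self.experiments:
            if dur <= 0:
                raise ValueError("experiment duration must be positive")
            if n < 6:
                raise ValueError("each experiment needs at least 6 points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be non-negative")
        if abs(sum(self.background_mix) - 1.0) > 1e-9:
            raise ValueError("background_mix must sum to 1")

    @property
    def n_genes(self) -> int:
        return (
            len(self.hub_specs)
            + sum(s.n_partners for s in self.hub_specs)
            + self.n_background_genes
        )


@dataclass(frozen=True)
class HubTruth:
    hub: str
    kind: HubKind
    n_interfaces: int
    partners: tuple[str, ...]
    table_class: str
    regulatory_class: str


@dataclass
class GroundTruth:
    """Generating-model truth for a synthetic cohort.

    ``labels`` maps each gene to periodic/static/stochastic; ``params`` maps
    each gene to its ``(amplitude, phase, baseline)`` (amplitude 0 for
    non-periodic genes); ``hubs`` records each hub's intended table and
    regulatory class.
    """

    labels: dict[str, str] = field(default_factory=dict)
    params: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    hubs: dict[str, HubTruth] = field(default_factory=dict)

    def genes_with_label(self, label: str) -> list[str]:
        return sorted(g for g, l in self.labels.items() if l == label)


def _hub_name(i: int) -> str:
    return f"HUB{i + 1:02d}"


def simulate_network(config: SimulationConfig) -> tuple[nx.Graph, GroundTruth]:
    """Build the cohort's interaction network and the truth skeleton.

    Each hub is the centre of a star of dedicated partners; background genes
    attach to one uniformly chosen earlier node (keeping the graph connected
    to the hub components) and gain extra background-background links with
    probability ``cross_link_prob``. Deterministic under the config seed.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    g: nx.Graph = nx.Graph()
    truth = GroundTruth()
    for i, spec in enumerate(config.hub_specs):
        hub = _hub_name(i)
        partners = tuple(f"{hub}P{k + 1:02d}" for k in range(spec.n_partners))
        g.add_node(hub)
        for p in partners:
            g.add_edge(hub, p)
        table_class, reg_class = _HUB_TRUTH[spec.kind]
        truth.hubs[hub] = HubTruth(
            hub=hub,
            kind=spec.kind,
            n_interfaces=spec.n_interfaces,
            partners=partners,
            table_class=table_class,
            regulatory_class=reg_class,
        )
    backgrounds = [f"BG{i + 1:03d}" for i in range(config.n_background_genes)]
    for b in backgrounds:
        # anchor to a non-hub node: hubs keep exactly their dedicated partners
        # as 1-step neighbours, so hub-kind truth stays consistent while the
        # graph remains connected to the hub components
        candidates = sorted(n for n in g.nodes if n not in truth.hubs)
        anchor = rng.choice(candidates)
        g.add_edge(b, str(anchor))
    for i in range(len(backgrounds)):
        for j in range(i + 1, len(backgrounds)):
            if rng.random() < config.cross_link_prob:
                g.add_edge(backgrounds[i], backgrounds[j])
    return g, truth


def _assign_labels(truth: GroundTruth, config: SimulationConfig, rng) -> None:
    """Assign periodic/static/stochastic labels and (A, phi, m) parameters."""
    T = config.period_T
    lo, hi = config.amplitude_range
    b_lo, b_hi = config.baseline_range

    def baseline() -> float:
        return float(rng.uniform(b_lo, b_hi))

    def amp() -> float:
        return float(rng.uniform(lo, hi))

    for hub, ht in sorted(truth.hubs.items()):
        if ht.kind == "dynamic_competitive":
            truth.labels[hub] = "periodic"
            truth.params[hub] = (amp(), float(rng.uniform(0, T)), baseline())
            for p in ht.partners:
                truth.labels[p] = "static"
                truth.params[p] = (0.0, 0.0, baseline())
        elif ht.kind == "static_noncompetitive":
            truth.labels[hub] = "static"
            truth.params[hub] = (0.0, 0.0, baseline())
            phi0 = float(rng.uniform(0, T))
            n = len(ht.partners)
            for k, p in enumerate(ht.partners):  # staggered peaks
                truth.labels[p] = "periodic"
                truth.params[p] = (amp(), (phi0 + k * T / n) % T, baseline())
        elif ht.kind == "coordinate":
            phi = float(rng.uniform(0, T))
            truth.labels[hub] = "periodic"
            truth.params[hub] = (amp(), phi, baseline())
            for p in ht.partners:
                truth.labels[p] = "periodic"
                truth.params[p] = (amp(), phi, baseline())
        else:  # stochastic
            for gene in (hub, *ht.partners):
                truth.labels[gene] = "stochastic"
                truth.params[gene] = (0.0, 0.0, baseline())
    for i in range(config.n_background_genes):
        gene = f"BG{i + 1:03d}"
        u = rng.random()
        p_per, p_stat, _ = config.background_mix
        if u < p_per:
            truth.labels[gene] = "periodic"
            truth.params[gene] = (amp(), float(rng.uniform(0, T)), baseline())
        elif u < p_per + p_stat:
            truth.labels[gene] = "static"
            truth.params[gene] = (0.0, 0.0, baseline())
        else:
            truth.labels[gene] = "stochastic"
            truth.params[gene] = (0.0, 0.0, baseline())


def _experiment_times(duration: float, n_points: int) -> np.ndarray:
    return np.linspace(0.0, duration, n_points)


def simulate_expression(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[list[ExpressionMatrix], GroundTruth]:
    """Generate one expression matrix per experiment from the truth skeleton.

    Stochastic genes are redrawn independently per experiment; periodic and
    static genes keep their parameters across experiments (same underlying
    biology, different sampling grids).
    """
    rng = np.random.default_rng([int(config.seed), 1])
    if not truth.labels:
        _assign_labels(truth, config, rng)
    genes = sorted(truth.labels)
    T = config.period_T
    sd = config.noise_sd
    rho = config.stochastic_rho
    stat_sd = sd / np.sqrt(1.0 - rho**2) if rho < 1 else sd
    matrices = []
    for e_idx, (duration, n_points) in enumerate(config.experiments):
        t = _experiment_times(duration, n_points)
        values = np.empty((len(genes), n_points))
        for gi, gene in enumerate(genes):
            label = truth.labels[gene]
            A, phi, m = truth.params[gene]
            if label == "periodic":
                base = m + A * np.cos(2 * np.pi * (t - phi) / T)
                values[gi] = base + rng.normal(0.0, sd, n_points)
            elif label == "static":
                values[gi] = m + rng.normal(0.0, sd, n_points)
            else:  # stochastic: stationary AR(1), independent per experiment
                x = np.empty(n_points)
                x[0] = rng.normal(0.0, stat_sd)
                innov = rng.normal(0.0, sd, n_points - 1)
                for k in range(1, n_points):
                    x[k] = rho * x[k - 1] + innov[k - 1]
                values[gi] = m + x
        matrices.append(
            ExpressionMatrix(
                experiment_id=f"exp{e_idx + 1}",
                genes=list(genes),
                times=t,
                values=values,
                missing=np.zeros_like(values, dtype=bool),
            )
        )
    return matrices, truth


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[nx.Graph, list[ExpressionMatrix], GroundTruth]:
    """Network + expression matrices + completed ground truth in one call."""
    config = config or SimulationConfig()
    network, truth = simulate_network(config)
    matrices, truth = simulate_expression(truth, config)
    return network, matrices, truth


def make_staggered_partners(
    n: int,
    config: SimulationConfig | None = None,
    amplitude: float = 0.8,
    baseline: float = 0.0,
    noise_sd: float | None = None,
) -> ExpressionMatrix:
    """Generate ``n`` partner series with troughs evenly phase-shifted by T/n.

    Emulates the staggered-partner pattern at static structural hubs: each
    partner dips below the rendering threshold at a different stretch of the
    cycle, so pairwise active-time overlap is low by construction. Uses the
    first experiment grid of ``config``; noise defaults to the config's
    ``noise_sd`` and can be forced to 0 for a noiseless construction.
    """
    if n < 2:
        raise ValueError("need n >= 2 partners")
    config = config or SimulationConfig()
    sd = config.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng([int(config.seed), 2])
    duration, n_points = config.experiments[0]
    t = _experiment_times(duration, n_points)
    T = config.period_T
    genes = [f"STAG{k + 1:02d}" for k in range(n)]
    values = np.empty((n, n_points))
    for k in range(n):
        phi = k * T / n  # peak at phi, trough at phi + T/2
        values[k] = (
            baseline
            + amplitude * np.cos(2 * np.pi * (t - phi) / T)
            + (rng.normal(0.0, sd, n_points) if sd > 0 else 0.0)
        )
    return ExpressionMatrix(
        experiment_id="staggered",
        genes=genes,
        times=t,
        values=values,
        missing=np.zeros_like(values, dtype=bool),
    )
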