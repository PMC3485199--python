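"""Hub-seeded ego networks and time-resolved node/edge visibility.

A node is *active* at a sampled time when its smoothed log2 ratio is at or
above an expression threshold (default -0.2; the published rendering hides
proteins *below* the threshold, so equality displays). Per-gene overrides
support the one documented exception, a low-amplitude periodic hub rendered
at -0.1. A network *frame* at time t shows the active nodes and exactly the
edges whose two endpoints are both active — proteins and their interactions
are hidden together. Frames exist only at sampled timepoints; the original
GUI's continuous interpolation is out of scope, so the exporter writes a
deterministic headless frame stack (JSON lines or one GraphML per
timepoint) instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .types import SmoothedMatrix, normalize_gene

__all__ = [
    "ActivityMask",
    "NetworkFrame",
    "ego_network",
    "activity_mask",
    "frame_at",
    "export_frames",
    "read_frames",
    "value_to_color",
    "DEFAULT_THRESHOLD",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = -0.2


def ego_network(network: nx.Graph, hub: str, steps: int = 1) -> nx.Graph:
    """Induced subgraph on all nodes within graph distance ``steps`` of the hub."""
    hub = normalize_gene(hub)
    if hub not in network:
        raise KeyError(f"hub not in network: {hub}")
    if steps not in (1, 2):
        raise ValueError("steps must be 1 or 2")
    return nx.ego_graph(network, hub, radius=steps)


@dataclass
class ActivityMask:
    """Boolean gene x time visibility under an expression threshold."""

    genes: list[str]
    times: np.ndarray
    active: np.ndarray
    values: np.ndarray
    missing: np.ndarray
    threshold_default: float
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}

    def threshold(self, gene: str) -> float:
        return self.overrides.get(normalize_gene(gene), self.threshold_default)

    def time_index(self, t: float) -> int:
        hits = np.flatnonzero(np.isclose(self.times, t, rtol=0.0, atol=1e-9))
        if hits.size == 0:
            raise ValueError(f"t={t} is not a sampled timepoint")
        return int(hits[0])

    def active_times(self, gene: str) -> frozenset[int]:
        """Indices of timepoints at which the gene is active."""
        i = self._index.get(normalize_gene(gene))
        if i is None:
            return frozenset()
        return frozenset(int(j) for j in np.flatnonzero(self.active[i]))

    def is_active(self, gene: str, t: float) -> bool:
        i = self._index.get(normalize_gene(gene))
        if i is None:
            return False
        return bool(self.active[i, self.time_index(t)])


def activity_mask(
    matrix: SmoothedMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    overrides: dict[str, float] | None = None,
) -> ActivityMask:
    """Threshold smoothed values into an :class:`ActivityMask`.

    The boundary is inclusive (value equal to the threshold is active);
    missing values are inactive. Overrides replace the default threshold for
    the listed genes only; an override for a gene absent from the matrix is
    ignored with a warning.
    """
    overrides = {normalize_gene(g): float(v) for g, v in (overrides or {}).items()}
    for g in sorted(set(overrides) - set(matrix.genes)):
        log.warning("threshold override for gene not in matrix, ignored: %s", g)
    overrides = {g: v for g, v in overrides.items() if g in matrix._index}
    thr = np.full(matrix.n_genes, float(threshold))
    for g, v in overrides.items():
        thr[matrix.index(g)] = v
    active = (matrix.values >= thr[:, None]) & ~matrix.missing
    return ActivityMask(
        genes=list(matrix.genes),
        times=matrix.times.copy(),
        active=active,
        values=matrix.values.copy(),
        missing=matrix.missing.copy(),
        threshold_default=float(threshold),
        overrides=overrides,
    )


@dataclass(frozen=True)
class NetworkFrame:
    """Visibility snapshot of a network at one sampled timepoint."""

    time: float
    visible_nodes: frozenset[str]
    visible_edges: frozenset[tuple[str, str]]
    node_values: dict[str, float]

    def __post_init__(self) -> None:
        for u, v in self.visible_edges:
            if u not in self.visible_nodes or v not in self.visible_nodes:
                raise ValueError(f"edge ({u},{v}) with hidden endpoint")


def frame_at(network: nx.Graph, mask: ActivityMask, t: float) -> NetworkFrame:
    """Frame of ``network`` at sampled time ``t`` (no interpolation)."""
    j = mask.time_index(t)
    visible = frozenset(
        g for g in network.nodes
        if g in mask._index and mask.active[mask._index[g], j]
    )
    edges = frozenset(
        tuple(sorted((u, v))) for u, v in network.edges()
        if u in visible and v in visible
    )
    values = {
        g: float(mask.values[mask._index[g], j])
        for g in sorted(visible)
    }
    return NetworkFrame(
        time=float(mask.times[j]),
        visible_nodes=visible,
        visible_edges=edges,
        node_values=values,
    )


def value_to_color(value: float, vmax: float) -> str:
    """Map a log2 ratio to the green/black/red gradient used for rendering.

    Anchors: ``-vmax`` pure green, 0 black, ``+vmax`` pure red.
    """
    if vmax <= 0:
        return "#000000"
    x = max(-1.0, min(1.0, value / vmax))
    if x >= 0:
        return f"#{int(round(255 * x)):02x}0000"
    return f"#00{int(round(255 * -x)):02x}00"


def export_frames(
    network: nx.Graph,
    mask: ActivityMask,
    path: str | Path,
    format: str = "json-lines",
) -> list[Path]:
    """Export one frame per sampled timepoint, deterministically ordered.

    ``json-lines``: one frame object per line (times ascending, nodes and
    edges lexicographic) written to ``path``. ``graphml-stack``: one GraphML
    file per timepoint under directory ``path``, named by frame index and
    time. A frame with an empty visible set is still written — absence is
    information. Node color metadata maps the value onto a green/black/red
    gradient anchored at (-max|v|, 0, +max|v|) over the mask.
    """
    path = Path(path)
    frames = [frame_at(network, mask, t) for t in mask.times]
    vmax = float(np.max(np.abs(mask.values[~mask.missing]))) if (~mask.missing).any() else 0.0
    if format == "json-lines":
        with open(path, "w") as fh:
            for fr in frames:
                obj = {
                    "time": fr.time,
                    "nodes": [
                        {
                            "id": g,
                            "value": fr.node_values[g],
                            "color": value_to_color(fr.node_values[g], vmax),
                        }
                        for g in sorted(fr.visible_nodes)
                    ],
                    "edges": [list(e) for e in sorted(fr.visible_edges)],
                }
                fh.write(json.dumps(obj, sort_keys=True) + "\n")
        return [path]
    if format == "graphml-stack":
        path.mkdir(parents=True, exist_ok=True)
        out: list[Path] = []
        for i, fr in enumerate(frames):
            g = nx.Graph(time=fr.time)
            for node in sorted(fr.visible_nodes):
                g.add_node(
                    node,
                    value=fr.node_values[node],
                    color=value_to_color(fr.node_values[node], vmax),
                )
            g.add_edges_from(sorted(fr.visible_edges))
            fp = path / f"frame_{i:04d}_t{fr.time:g}.graphml"
            nx.write_graphml(g, fp)
            out.append(fp)
        return out
    raise ValueError(f"unknown frame format: {format!r}")


def read_frames(path: str | Path, format: str = "json-lines") -> list[NetworkFrame]:
    """Re-read an exported frame stack into :class:`NetworkFrame` objects."""
    path = Path(path)
    frames: list[NetworkFrame] = []
    if format == "json-lines":
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                frames.append(
                    NetworkFrame(
                        time=float(obj["time"]),
                        visible_nodes=frozenset(n["id"] for n in obj["nodes"]),
                        visible_edges=frozenset(
                            tuple(sorted(e)) for e in obj["edges"]
                        ),
                        node_values={n["id"]: float(n["value"]) for n in obj["nodes"]},
                    )
                )
        return frames
    if format == "graphml-stack":
        for fp in sorted(Path(path).glob("frame_*.graphml")):
            g = nx.read_graphml(fp)
            frames.append(
                NetworkFrame(
                    time=float(g.graph["time"]),
                    visible_nodes=frozenset(g.nodes),
                    visible_edges=frozenset(tuple(sorted(e)) for e in g.edges()),
                    node_values={n: float(d["value"]) for n, d in g.nodes(data=True)},
                )
            )
        return frames
    raise ValueError(f"unknown frame format: {format!r}")
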