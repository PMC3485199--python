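"""Readers and writers for expression matrices, interaction networks and the
packaged hub-annotation fixtures.

Formats
-------
Expression: TSV, one gene per row, first column the gene symbol, header row
carrying sampling times in minutes (``dialect="minutes"``) or headers with a
numeric suffix such as Spellman-style ``alpha0, alpha7, ...``
(``dialect="prefixed"``). Unparseable cells become missing values, never
errors.

Networks: SIF (``A<tab>pp<tab>B``, extra targets allowed), two-column TSV
edge lists, or GraphML. Graphs are undirected and simple: reciprocal
duplicates collapse to one edge and self-loops are dropped with a logged
warning (interface analysis concerns hetero-interactions only).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import ExpressionMatrix, normalize_gene

__all__ = [
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "HubRecord",
    "load_singlish_hubs",
    "load_gdi1_partners",
    "gdi1_network",
]

log = logging.getLogger(__name__)

_SUFFIX_NUMBER = re.compile(r"(-?\d+(?:\.\d+)?)\s*$")


def _parse_time_header(labels: list[str], dialect: str) -> np.ndarray:
    times = []
    for lab in labels:
        lab = str(lab).strip()
        if dialect == "minutes":
            try:
                times.append(float(lab))
            except ValueError as exc:
                raise ValueError(f"non-numeric time header: {lab!r}") from exc
        elif dialect == "prefixed":
            m = _SUFFIX_NUMBER.search(lab)
            if m is None:
                raise ValueError(f"no numeric suffix in time header: {lab!r}")
            times.append(float(m.group(1)))
        else:
            raise ValueError(f"unknown expression dialect: {dialect!r}")
    arr = np.asarray(times, dtype=float)
    if np.any(np.diff(arr) <= 0):
        raise ValueError("time header is not strictly increasing")
    return arr


def read_expression(
    path: str | Path,
    dialect: str = "minutes",
    experiment_id: str | None = None,
) -> ExpressionMatrix:
    """Read a gene x timepoint TSV into an :class:`ExpressionMatrix`.

    Unparseable or empty cells become ``missing=True`` at that position;
    a duplicate gene row or a non-increasing time header is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene column plus time columns")
    times = _parse_time_header(list(df.columns[1:]), dialect)
    genes = [normalize_gene(g) for g in df.iloc[:, 0]]
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise ValueError(f"{path}: duplicate gene row: {g}")
        seen.add(g)
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    missing = np.zeros(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            try:
                v = float(cell)
            except ValueError:
                v = np.nan
            if cell == "" or not np.isfinite(v):
                values[i, j] = 0.0
                missing[i, j] = True
            else:
                values[i, j] = v
    return ExpressionMatrix(
        experiment_id=experiment_id or path.stem,
        genes=genes,
        times=times,
        values=values,
        missing=missing,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; missing cells are written empty.

    Float formatting uses Python's shortest round-trip repr so a
    write/read cycle reproduces the matrix exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(repr(float(t)) for t in matrix.times) + "\n")
        for i, g in enumerate(matrix.genes):
            cells = [
                "" if matrix.missing[i, j] else repr(float(matrix.values[i, j]))
                for j in range(matrix.n_times)
            ]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


def _infer_network_dialect(path: Path) -> str:
    suf = path.suffix.lower()
    if suf == ".sif":
        return "sif"
    if suf == ".graphml":
        return "graphml"
    return "tsv"


def _add_edge(g: nx.Graph, a: str, b: str, loops: list[str]) -> None:
    a, b = normalize_gene(a), normalize_gene(b)
    if a == b:
        loops.append(a)
        g.add_node(a)
        return
    g.add_node(a)
    g.add_node(b)
    g.add_edge(a, b)


def read_network(path: str | Path, dialect: str | None = None) -> nx.Graph:
    """Read an undirected simple interaction network.

    ``A-B`` and ``B-A`` collapse to a single edge; self-loops are dropped
    (one logged warning per file). Malformed lines raise with the line
    number.
    """
    path = Path(path)
    dialect = dialect or _infer_network_dialect(path)
    g: nx.Graph = nx.Graph()
    loops: list[str] = []
    if dialect == "graphml":
        raw = nx.read_graphml(path)
        for n in raw.nodes:
            g.add_node(normalize_gene(str(n)))
        for u, v in raw.edges():
            _add_edge(g, str(u), str(v), loops)
    elif dialect in ("sif", "tsv"):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                toks = line.split("\t") if "\t" in line else line.split()
                toks = [t for t in (tok.strip() for tok in toks) if t]
                if dialect == "sif":
                    if len(toks) == 1:
                        g.add_node(normalize_gene(toks[0]))
                        continue
                    if len(toks) < 3:
                        raise ValueError(
                            f"{path}:{lineno}: malformed SIF line: {line!r}"
                        )
                    src = toks[0]
                    for tgt in toks[2:]:
                        _add_edge(g, src, tgt, loops)
                else:
                    if len(toks) != 2:
                        raise ValueError(
                            f"{path}:{lineno}: expected two columns, got {len(toks)}"
                        )
                    _add_edge(g, toks[0], toks[1], loops)
    else:
        raise ValueError(f"unknown network dialect: {dialect!r}")
    if loops:
        log.warning(
            "%s: dropped %d self-loop(s) (%s)", path, len(loops), ", ".join(sorted(set(loops)))
        )
    return g


def write_network(g: nx.Graph, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    dialect = dialect or _infer_network_dialect(path)
    if dialect == "graphml":
        nx.write_graphml(g, path)
        return
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            if dialect == "sif":
                fh.write(f"{u}\tpp\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\n")
        for n in sorted(g.nodes):
            if g.degree(n) == 0 and dialect == "sif":
                fh.write(f"{n}\n")


@dataclass(frozen=True)
class HubRecord:
    """One row of the packaged singlish-hub annotation table.

    ``n_interfaces`` is the number of structurally distinct interaction
    interfaces (1 or 2 by definition of a singlish hub); ``reported_class``
    is the published Dynamic/Static call, ``"missing"`` where the survey
    left the hub unclassified (noisy or inconsistent expression).
    """

    hub: str
    n_interfaces: int
    domains: tuple[str, ...]
    functional_group: str
    reported_class: str

    def __post_init__(self) -> None:
        if self.n_interfaces not in (1, 2):
            raise ValueError("singlish hubs have 1 or 2 interfaces")
        if self.reported_class not in ("Dynamic", "Static", "missing"):
            raise ValueError(f"bad reported_class: {self.reported_class!r}")


def _fixture_path(name: str):
    return resources.files("hubcycle.data").joinpath(name)


def load_singlish_hubs() -> list[HubRecord]:
    """Load the packaged annotation of the 36 singlish-interface hubs of
    *S. cerevisiae* (hub, interface count, Pfam domain strings, functional
    group, published Dynamic/Static classification)."""
    records = []
    with resources.as_file(_fixture_path("singlish_hubs.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    for _, row in df.iterrows():
        cls = row["reported_class"].strip()
        records.append(
            HubRecord(
                hub=normalize_gene(row["hub"]),
                n_interfaces=int(row["n_interfaces"]),
                domains=tuple(d for d in row["domains"].split(",") if d),
                functional_group=row["functional_group"],
                reported_class="missing" if cls in ("-", "") else cls,
            )
        )
    return records


def load_gdi1_partners() -> dict[str, str]:
    """Load the packaged Gdi1 partner list: partner symbol -> expression
    class (``periodic`` for the dynamically expressed partners, else
    ``aperiodic``)."""
    with resources.as_file(_fixture_path("gdi1_partners.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    return {
        normalize_gene(r["partner"]): r["expression_class"].strip()
        for _, r in df.iterrows()
    }


def gdi1_network() -> nx.Graph:
    """Hub-and-spoke network of Gdi1 and its packaged interaction partners."""
    g = nx.Graph()
    hub = "GDI1"
    g.add_node(hub)
    for partner in load_gdi1_partners():
        g.add_edge(hub, partner)
    return g
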