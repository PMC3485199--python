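"""Core in-memory containers shared across the pipeline.

Expression data are log2 sample/reference ratios from synchronized-culture
time courses, one matrix per synchronization experiment, with a minutes axis
and an explicit missing-value mask (microarray time courses routinely have
unmeasured cells; we carry them as a mask and never impute at read time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "normalize_gene",
    "ExpressionMatrix",
    "SmoothedMatrix",
]


def normalize_gene(name: str) -> str:
    """Normalize a gene identifier to the uppercase standard symbol.

    The literature mixes ``Cla4`` / ``CLA4`` conventions; all joins between
    networks, expression matrices and annotation tables are done on the
    normalized form.
    """
    if name is None:
        raise ValueError("gene identifier is None")
    norm = str(name).strip().upper()
    if not norm:
        raise ValueError("empty gene identifier")
    if any(c.isspace() for c in norm):
        raise ValueError(f"gene identifier contains whitespace: {name!r}")
    return norm


@dataclass
class ExpressionMatrix:
    """Gene x timepoint log2-ratio matrix for one synchronization experiment.

    Attributes
    ----------
    experiment_id : str
        Label of the synchronization experiment (e.g. ``"alpha"``).
    genes : list of str
        Normalized gene symbols, one per row, unique.
    times : ndarray of float
        Sampling times in minutes, strictly increasing.
    values : ndarray, shape (n_genes, n_times)
        log2 expression ratios; finite wherever ``missing`` is False.
    missing : ndarray of bool, same shape
        True where no usable measurement exists.
    """

    experiment_id: str
    genes: list[str]
    times: np.ndarray
    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genes = [normalize_gene(g) for g in self.genes]
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (len(self.genes), self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.genes)}, {self.times.size})"
            )
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask shape does not match values")
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                raise ValueError(f"duplicate gene row: {g}")
            seen.add(g)
        # Any non-finite measured cell is a contract violation; mask it instead.
        bad = ~np.isfinite(self.values) & ~self.missing
        if bad.any():
            raise ValueError("non-finite values present where missing is False")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    def __contains__(self, gene: str) -> bool:
        return normalize_gene(gene) in self._index

    def index(self, gene: str) -> int:
        return self._index[normalize_gene(gene)]

    def row(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(values, missing)`` for one gene."""
        i = self.index(gene)
        return self.values[i], self.missing[i]

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        idx = [self.index(g) for g in genes]
        return ExpressionMatrix(
            experiment_id=self.experiment_id,
            genes=[self.genes[i] for i in idx],
            times=self.times.copy(),
            values=self.values[idx].copy(),
            missing=self.missing[idx].copy(),
        )


@dataclass
class SmoothedMatrix(ExpressionMatrix):
    """An :class:`ExpressionMatrix` after local-regression smoothing.

    ``unsmoothable`` lists genes with too few usable points for a local fit;
    their rows are all-missing and they propagate to *unclassifiable*
    downstream rather than raising.
    """

    span: float = 0.5
    degree: int = 2
    unsmoothable: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (0.0 < self.span <= 1.0):
            raise ValueError("span must be in (0, 1]")
        self.unsmoothable = frozenset(normalize_gene(g) for g in self.unsmoothable)
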