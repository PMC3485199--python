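"""Dynamic/Static classification of singlish hubs and regulatory classes.

Classification rules (applied to the combined periodicity verdicts of a hub
and its direct, 1-step interaction partners):

* periodic hub -> **Dynamic**;
* aperiodic hub with at least one periodic partner -> **Static**;
* aperiodic hub whose partners are all aperiodic -> **unassigned** (the
  published Static definition is conditional on a periodic partner and
  otherwise silent; these hubs are reported but excluded from the
  competitive/non-competitive tallies);
* unclassifiable hub (missing or low-quality expression) -> **not_classified**.

Regulatory classes: a Dynamic hub with at least one aperiodic partner is
**competitive** (its constitutively present partners compete for the hub's
one or two interfaces whenever the hub is expressed); a Static hub is
**non_competitive** (its periodic partners are expressed at regulated,
often staggered, times); anything else — including a Dynamic hub whose
whole neighbourhood oscillates in phase with it, the co-ordinate-regulation
pattern of the rRNA-processing hubs — is **none**.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import HubRecord
from .types import normalize_gene

__all__ = [
    "HubClassification",
    "classify_hub",
    "regulatory_class",
    "build_classification",
    "tabulate",
    "summarize_reported",
]

TABLE_CLASSES = ("Dynamic", "Static", "unassigned", "not_classified")
REGULATORY_CLASSES = ("competitive", "non_competitive", "none")
_VERDICTS = ("periodic", "aperiodic", "unclassifiable")


@dataclass(frozen=True)
class HubClassification:
    hub: str
    n_interfaces: int
    hub_verdict: str
    n_partners: int
    n_periodic_partners: int
    n_aperiodic_partners: int
    n_unclassifiable_partners: int
    table_class: str
    regulatory_class: str

    def __post_init__(self) -> None:
        if self.n_interfaces not in (1, 2):
            raise ValueError("n_interfaces must be 1 or 2")
        if self.hub_verdict not in _VERDICTS:
            raise ValueError(f"bad hub verdict: {self.hub_verdict!r}")
        parts = (
            self.n_periodic_partners
            + self.n_aperiodic_partners
            + self.n_unclassifiable_partners
        )
        if parts != self.n_partners:
            raise ValueError("partner counts do not sum to n_partners")
        if self.table_class not in TABLE_CLASSES:
            raise ValueError(f"bad table class: {self.table_class!r}")
        if self.regulatory_class not in REGULATORY_CLASSES:
            raise ValueError(f"bad regulatory class: {self.regulatory_class!r}")
        if (self.table_class == "Dynamic") != (self.hub_verdict == "periodic"):
            raise ValueError("Dynamic iff hub verdict periodic")
        if self.table_class == "Static" and (
            self.hub_verdict != "aperiodic" or self.n_periodic_partners < 1
        ):
            raise ValueError("Static requires aperiodic hub with a periodic partner")


def classify_hub(hub_verdict: str, partner_verdicts: Sequence[str]) -> str:
    """Table class from the hub's verdict and its direct partners' verdicts."""
    if hub_verdict not in _VERDICTS:
        raise ValueError(f"bad hub verdict: {hub_verdict!r}")
    for v in partner_verdicts:
        if v not in _VERDICTS:
            raise ValueError(f"bad partner verdict: {v!r}")
    if hub_verdict == "periodic":
        return "Dynamic"
    if hub_verdict == "unclassifiable":
        return "not_classified"
    if any(v == "periodic" for v in partner_verdicts):
        return "Static"
    return "unassigned"


def regulatory_class(classification: HubClassification) -> str:
    """Competitive / non-competitive / none from a computed classification."""
    if (
        classification.table_class == "Dynamic"
        and classification.n_aperiodic_partners >= 1
    ):
        return "competitive"
    if classification.table_class == "Static":
        return "non_competitive"
    return "none"


def build_classification(
    hub: str,
    n_interfaces: int,
    hub_verdict: str,
    partner_verdicts: Sequence[str],
) -> HubClassification:
    """Assemble the full record for one hub (table class, partner tallies,
    regulatory class)."""
    counts = Counter(partner_verdicts)
    table = classify_hub(hub_verdict, partner_verdicts)
    cls = HubClassification(
        hub=normalize_gene(hub),
        n_interfaces=n_interfaces,
        hub_verdict=hub_verdict,
        n_partners=len(partner_verdicts),
        n_periodic_partners=counts.get("periodic", 0),
        n_aperiodic_partners=counts.get("aperiodic", 0),
        n_unclassifiable_partners=counts.get("unclassifiable", 0),
        table_class=table,
        regulatory_class="none",
    )
    return HubClassification(**{**cls.__dict__, "regulatory_class": regulatory_class(cls)})


def tabulate(classifications: Iterable[HubClassification]) -> dict:
    """Exact counts per table class and per regulatory class.

    Raises on a duplicate hub. Counts always sum to the number of hubs.
    """
    table = {c: 0 for c in TABLE_CLASSES}
    reg = {c: 0 for c in REGULATORY_CLASSES}
    seen: set[str] = set()
    n = 0
    for c in classifications:
        if c.hub in seen:
            raise ValueError(f"duplicate hub: {c.hub}")
        seen.add(c.hub)
        table[c.table_class] += 1
        reg[c.regulatory_class] += 1
        n += 1
    return {"total": n, "table_class": table, "regulatory_class": reg}


def summarize_reported(records: Iterable[HubRecord]) -> dict:
    """Tally the published Dynamic/Static/unclassified annotations of the
    packaged singlish-hub table (hyphen rows count as ``not_classified``)."""
    counts = {"Dynamic": 0, "Static": 0, "not_classified": 0}
    seen: set[str] = set()
    total = 0
    for r in records:
        if r.hub in seen:
            raise ValueError(f"duplicate hub: {r.hub}")
        seen.add(r.hub)
        key = "not_classified" if r.reported_class == "missing" else r.reported_class
        counts[key] += 1
        total += 1
    return {"total": total, **counts}
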