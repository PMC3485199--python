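"""End-to-end pipeline: read -> smooth -> periodicity -> classify -> compete
-> frames, with deterministic, manifest-stamped report files.

The library entry point is :func:`analyze_cohort` (in-memory objects in,
results out); :func:`run_pipeline` wraps it with file I/O, per-stage
logging and a run manifest, and is what the command-line interface calls.
Reruns with the same config and seed are byte-identical apart from the
manifest timestamp line.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import __version__
from .classify import HubClassification, build_classification, tabulate
from .competition import competition_profile, flag_staggered, partner_overlap
from .io import load_singlish_hubs, read_expression, read_network
from .periodicity import (
    DEFAULT_PERIOD_GRID,
    PeriodicityScore,
    call_gene,
    combine_calls,
    estimate_period,
    score_gene,
)
from .smoothing import smooth_matrix
from .temporal import activity_mask, ego_network, export_frames
from .types import ExpressionMatrix, normalize_gene

__all__ = ["RunConfig", "CohortResults", "analyze_cohort", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    network: str
    expression: list[str]
    out_dir: str
    hubs: str = "fixture"  # packaged singlish-hub table, or a TSV path
    expression_dialect: str = "minutes"
    span: float = 0.5
    degree: int = 2
    alpha: float = 0.05
    min_amplitude: float = 0.2
    n_perm: int = 1000
    period_grid: list[float] = field(default_factory=lambda: list(DEFAULT_PERIOD_GRID))
    threshold: float = -0.2
    overrides: dict[str, float] = field(default_factory=dict)
    steps: int = 1
    frames: str = "json-lines"  # or "graphml-stack" / "none"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }


@dataclass
class CohortResults:
    periods: dict[str, float]
    scores: list[PeriodicityScore]
    per_experiment_calls: dict[str, dict[str, str]]  # gene -> experiment -> call
    combined_calls: dict[str, str]
    classifications: list[HubClassification]
    counts: dict
    competition: list[dict]  # per hub x experiment summary rows
    frames_written: list[Path] = field(default_factory=list)


def _load_hub_table(spec: str) -> dict[str, int]:
    """Map hub -> interface count, from the packaged table or a custom TSV."""
    if spec == "fixture":
        return {r.hub: r.n_interfaces for r in load_singlish_hubs()}
    import pandas as pd

    df = pd.read_csv(spec, sep="\t", dtype=str)
    return {
        normalize_gene(r["hub"]): int(r["n_interfaces"]) for _, r in df.iterrows()
    }


def analyze_cohort(
    network: nx.Graph,
    matrices: list[ExpressionMatrix],
    hub_interfaces: dict[str, int],
    *,
    span: float = 0.5,
    degree: int = 2,
    alpha: float = 0.05,
    min_amplitude: float = 0.2,
    n_perm: int = 1000,
    period_grid=DEFAULT_PERIOD_GRID,
    threshold: float = -0.2,
    overrides: dict[str, float] | None = None,
    steps: int = 1,
    seed: int = 0,
    frames_dir: str | Path | None = None,
    frames_format: str = "json-lines",
) -> CohortResults:
    """Run the full analysis on in-memory inputs.

    Per-gene permutation streams are seeded as ``(seed, experiment_index,
    gene_index)`` so a fixed master seed reproduces every score. Partners
    are the hub's 1-step neighbours; the 1-or-2-step ego networks are used
    only for frame export context.
    """
    t0 = time.perf_counter()
    smoothed = [smooth_matrix(m, span=span, degree=degree) for m in matrices]
    log.info("smoothing: %d experiments in %.2fs", len(smoothed), time.perf_counter() - t0)

    periods: dict[str, float] = {}
    for sm in smoothed:
        periods[sm.experiment_id] = estimate_period(sm, period_grid)
        log.info("period[%s] = %g min", sm.experiment_id, periods[sm.experiment_id])

    scores: list[PeriodicityScore] = []
    per_exp: dict[str, dict[str, str]] = {}
    for e_idx, sm in enumerate(smoothed):
        T = periods[sm.experiment_id]
        for g_idx, gene in enumerate(sm.genes):
            sc = score_gene(
                sm.times,
                sm.values[g_idx],
                T,
                missing=sm.missing[g_idx],
                n_perm=n_perm,
                seed=[int(seed), e_idx, g_idx],
                gene=gene,
                experiment_id=sm.experiment_id,
            )
            scores.append(sc)
            per_exp.setdefault(gene, {})[sm.experiment_id] = call_gene(
                sc, alpha=alpha, min_amplitude=min_amplitude
            )
    combined = {g: combine_calls(calls) for g, calls in sorted(per_exp.items())}
    log.info("periodicity: %d genes scored", len(combined))

    def verdict(gene: str) -> str:
        return combined.get(gene, "unclassifiable")

    classifications = []
    for hub in sorted(hub_interfaces):
        if hub not in network:
            log.warning("hub absent from network, skipped: %s", hub)
            continue
        partners = sorted(network.neighbors(hub))
        classifications.append(
            build_classification(
                hub,
                hub_interfaces[hub],
                verdict(hub),
                [verdict(p) for p in partners],
            )
        )
    counts = tabulate(classifications)

    masks = {
        sm.experiment_id: activity_mask(sm, threshold=threshold, overrides=overrides)
        for sm in smoothed
    }
    competition_rows: list[dict] = []
    for cls in classifications:
        for exp_id in sorted(masks):
            mask = masks[exp_id]
            prof = competition_profile(cls.hub, network, mask, cls.n_interfaces)
            row = {
                "hub": cls.hub,
                "experiment": exp_id,
                "n_partners": len(prof.partners),
                "max_simultaneous": prof.max_simultaneous,
                "fraction_time_competitive": prof.fraction_time_competitive,
                "fraction_time_competitive_hub_active": prof.fraction_time_competitive_hub_active,
            }
            if len(prof.partners) >= 2:
                ov = partner_overlap(mask, prof.partners)
                row["staggered_score"] = ov.staggered_score
                row["staggered"] = flag_staggered(ov)
            else:
                row["staggered_score"] = float("nan")
                row["staggered"] = False
            competition_rows.append(row)

    frames_written: list[Path] = []
    if frames_dir is not None and frames_format != "none":
        frames_dir = Path(frames_dir)
        frames_dir.mkdir(parents=True, exist_ok=True)
        for cls in classifications:
            ego = ego_network(network, cls.hub, steps=steps)
            for exp_id in sorted(masks):
                if frames_format == "json-lines":
                    out = frames_dir / f"{cls.hub}_{exp_id}.jsonl"
                else:
                    out = frames_dir / f"{cls.hub}_{exp_id}"
                frames_written.extend(
                    export_frames(ego, masks[exp_id], out, format=frames_format)
                )

    return CohortResults(
        periods=periods,
        scores=scores,
        per_experiment_calls=per_exp,
        combined_calls=combined,
        classifications=classifications,
        counts=counts,
        competition=competition_rows,
        frames_written=frames_written,
    )


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(c) for c in row) + "\n")


def run_pipeline(config: RunConfig) -> CohortResults:
    """Execute the pipeline from a :class:`RunConfig` and write report files.

    Outputs under ``config.out_dir``: ``scores.tsv``, ``calls.tsv``,
    ``classifications.tsv``, ``summary.tsv``, ``competition.tsv``, a frame
    stack under ``frames/`` and ``manifest.txt`` (timestamp, config echo,
    versions, seed). Any stage error aborts with the stage name and the
    offending entity.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        network = read_network(config.network)
        matrices = [
            read_expression(p, dialect=config.expression_dialect)
            for p in config.expression
        ]
        hub_interfaces = _load_hub_table(config.hubs)
        stage = "analyze"
        results = analyze_cohort(
            network,
            matrices,
            hub_interfaces,
            span=config.span,
            degree=config.degree,
            alpha=config.alpha,
            min_amplitude=config.min_amplitude,
            n_perm=config.n_perm,
            period_grid=config.period_grid,
            threshold=config.threshold,
            overrides=config.overrides,
            steps=config.steps,
            seed=config.seed,
            frames_dir=out / "frames" if config.frames != "none" else None,
            frames_format=config.frames,
        )
        stage = "report"
        _write_reports(out, config, results)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def _write_reports(out: Path, config: RunConfig, results: CohortResults) -> None:
    exp_ids = sorted(results.periods)
    _write_tsv(
        out / "scores.tsv",
        ["gene", "experiment", "period_T", "amplitude_A", "phase_phi",
         "r_squared", "p_perm", "n_usable", "usable", "call"],
        [
            [s.gene, s.experiment_id, s.period_T, s.amplitude_A, s.phase_phi,
             s.r_squared, s.p_perm, s.n_usable, s.usable,
             results.per_experiment_calls[s.gene][s.experiment_id]]
            for s in sorted(results.scores, key=lambda s: (s.gene, s.experiment_id))
        ],
    )
    _write_tsv(
        out / "calls.tsv",
        ["gene", *exp_ids, "combined"],
        [
            [g, *[results.per_experiment_calls[g].get(e, "unusable") for e in exp_ids],
             results.combined_calls[g]]
            for g in sorted(results.combined_calls)
        ],
    )
    _write_tsv(
        out / "classifications.tsv",
        ["hub", "n_interfaces", "hub_verdict", "n_partners",
         "n_periodic_partners", "n_aperiodic_partners",
         "n_unclassifiable_partners", "table_class", "regulatory_class"],
        [
            [c.hub, c.n_interfaces, c.hub_verdict, c.n_partners,
             c.n_periodic_partners, c.n_aperiodic_partners,
             c.n_unclassifiable_partners, c.table_class, c.regulatory_class]
            for c in sorted(results.classifications, key=lambda c: c.hub)
        ],
    )
    counts = results.counts
    _write_tsv(
        out / "summary.tsv",
        ["category", "class", "count"],
        (
            [["total", "hubs", counts["total"]]]
            + [["table_class", k, v] for k, v in counts["table_class"].items()]
            + [["regulatory_class", k, v] for k, v in counts["regulatory_class"].items()]
        ),
    )
    comp_cols = ["hub", "experiment", "n_partners", "max_simultaneous",
                 "fraction_time_competitive",
                 "fraction_time_competitive_hub_active",
                 "staggered_score", "staggered"]
    _write_tsv(
        out / "competition.tsv",
        comp_cols,
        [[r[c] for c in comp_cols]
         for r in sorted(results.competition, key=lambda r: (r["hub"], r["experiment"]))],
    )
    with open(out / "manifest.txt", "w") as fh:
        fh.write(f"generated_at: {time.strftime('%Y-%m-%dT%H:%M:%S')}\n")
        fh.write(f"hubcycle_version: {__version__}\n")
        fh.write(f"numpy_version: {np.__version__}\n")
        fh.write(f"networkx_version: {nx.__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write("config:\n")
        fh.write(yaml.safe_dump(config.to_dict(), sort_keys=True))
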