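"""End-to-end orchestration of the six analysis phases.

read inputs -> (optional) promoter de-duplication -> hits (read or scan)
-> TFBS-sequence matrix -> over-representation filter -> sparsity filter
-> sequence/TFBS PMI -> importance selection -> hit restriction
-> same-type overlap resolution -> pair enumeration -> pair scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import importance as imp
from . import pair_scoring, pairing, site_filters, tsm as tsm_mod
from .exceptions import (
    InsufficientPairsError,
    NoHitsError,
    NoSequencesError,
    NoSurvivingColumnsError,
)
from .pair_scoring import PairScoreTable
from .pairing import PairCountTable
from .tfbs_io import (
    Pwm,
    SequenceRecord,
    TfbsHit,
    deduplicate_promoters,
    scan_records,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Effective parameters of one run; defaults mirror the headline setup."""

    d_min: int = 5
    d_max: int = 20
    max_overlap: int = 4
    z_threshold: float = 3.0
    min_score: float = 0.85
    filter_overrepresented: bool = True
    filter_sparse: bool = True
    filter_importance: bool = True
    filter_same_type_overlaps: bool = True
    dedup_promoters: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        filters = raw.pop("filters", {})
        mapping = {
            "overrepresented": "filter_overrepresented",
            "sparse": "filter_sparse",
            "importance": "filter_importance",
            "same_type_overlaps": "filter_same_type_overlaps",
            "dedup_promoters": "dedup_promoters",
        }
        for key, value in filters.items():
            if key not in mapping:
                raise ValueError(f"unknown filter switch {key!r}")
            raw[mapping[key]] = value
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    scores: PairScoreTable
    counts: PairCountTable
    tsm_raw: tsm_mod.TsmMatrix
    tsm_filtered: tsm_mod.TsmMatrix
    importance: imp.ImportanceTable
    hits_used: list[TfbsHit]
    config: PipelineConfig
    log: list[str] = field(default_factory=list)


def _log(lines: list[str], msg: str) -> None:
    logger.info(msg)
    lines.append(msg)


def run_pipeline(
    records: Sequence[SequenceRecord],
    hits: Optional[Sequence[TfbsHit]] = None,
    pwms: Optional[Sequence[Pwm]] = None,
    consensus_motifs: Optional[dict[str, str]] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full analysis on a sequence set.

    Binding sites come from ``hits`` (a precomputed table) or from scanning
    with ``pwms`` / ``consensus_motifs``.
    """
    cfg = config or PipelineConfig()
    if cfg.d_min > cfg.d_max:
        raise ValueError("d_min must not exceed d_max")
    lines: list[str] = [f"parameters: {cfg.to_dict()}"]
    if not records:
        raise NoSequencesError("no sequences")

    if cfg.dedup_promoters:
        before = len(records)
        records = deduplicate_promoters(records)
        _log(lines, f"promoter dedup: {before} -> {len(records)} sequences")
        if not records:
            raise NoSequencesError("no sequences after promoter de-duplication")

    if hits is None:
        if not pwms and not consensus_motifs:
            raise NoHitsError("no hits supplied and nothing to scan with")
        hits = scan_records(records, pwms=pwms, consensus_motifs=consensus_motifs,
                            min_score=cfg.min_score)
        _log(lines, f"scanner produced {len(hits)} hits")
    hits = list(hits)
    if not hits:
        raise NoHitsError("no hits")
    _log(lines, f"input: {len(records)} sequences, {len(hits)} hits")

    raw = tsm_mod.build_tsm(hits, records)
    _log(lines, f"TSM: {raw.table.shape[0]} x {raw.table.shape[1]}")
    filtered = raw
    if cfg.filter_overrepresented:
        filtered = tsm_mod.filter_overrepresented(filtered)
        _log(
            lines,
            f"over-representation filter (sigma={filtered.sigma:.4f}): "
            f"{raw.table.shape[1]} -> {filtered.table.shape[1]} columns",
        )
    n_before = filtered.table.shape[1]
    if cfg.filter_sparse:
        if n_before == 0:
            raise NoSurvivingColumnsError("no surviving columns")
        filtered = tsm_mod.filter_sparse(filtered)
        _log(lines, f"sparsity filter: {n_before} -> {filtered.table.shape[1]} columns")
    if filtered.table.shape[1] == 0:
        raise NoSurvivingColumnsError("no surviving columns")

    table = imp.sequence_tfbs_pmi(filtered)
    table = imp.select_important(table)
    if cfg.filter_importance:
        hits_kept = imp.restrict_hits(hits, table)
        _log(lines, f"importance restriction: {len(hits)} -> {len(hits_kept)} hits")
    else:
        surviving = set(filtered.col_ids)
        hits_kept = [h for h in hits if h.matrix_id in surviving]
        _log(
            lines,
            "importance restriction disabled; "
            f"{len(hits)} -> {len(hits_kept)} hits (column filter only)",
        )

    if cfg.filter_same_type_overlaps:
        n_before_h = len(hits_kept)
        hits_kept = site_filters.resolve_same_type_overlaps(hits_kept, records)
        _log(lines, f"same-type overlap filter: {n_before_h} -> {len(hits_kept)} hits")

    counts = pairing.enumerate_pairs(
        hits_kept,
        d_min=cfg.d_min,
        d_max=cfg.d_max,
        max_overlap=cfg.max_overlap,
        sequence_ids=[r.id for r in records],
        keep_instances=True,
    )
    _log(
        lines,
        f"pairing: {counts.total} pair instances over {len(counts.pooled)} pair types",
    )
    if len(counts.pooled) < 2:
        raise InsufficientPairsError("fewer than 2 observed pairs")

    scores = pair_scoring.score_pairs(counts, z_threshold=cfg.z_threshold)
    n_sig = int(scores.frame.significant.sum())
    _log(lines, f"scoring: {len(scores.frame)} scored pairs, {n_sig} significant")
    return PipelineResult(
        scores=scores,
        counts=counts,
        tsm_raw=raw,
        tsm_filtered=filtered,
        importance=table,
        hits_used=hits_kept,
        config=cfg,
        log=lines,
    )


def network_tables(scores: PairScoreTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list (significant pairs) and node-degree table of the network."""
    sig = scores.significant
    edges = sig[["type_a", "type_b", "zscore"]].reset_index(drop=True)
    graph = nx.Graph()
    for _, row in edges.iterrows():
        graph.add_edge(row.type_a, row.type_b)
    degrees = pd.DataFrame(
        sorted(graph.degree, key=lambda kv: (-kv[1], kv[0])),
        columns=["node", "degree"],
    )
    return edges, degrees


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write pairs.tsv, significant_pairs.tsv, network tables and run.log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.10g")
    result.scores.frame.to_csv(outdir / "pairs.tsv", **fmt)
    result.scores.significant.to_csv(outdir / "significant_pairs.tsv", **fmt)
    edges, degrees = network_tables(result.scores)
    edges.to_csv(outdir / "network_edges.tsv", **fmt)
    degrees.to_csv(outdir / "node_degrees.tsv", **fmt)
    (outdir / "run.log").write_text("\n".join(result.log) + "\n")
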