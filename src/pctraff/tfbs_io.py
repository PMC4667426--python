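"""Sequence, matrix and binding-site I/O, plus a stand-in PWM scanner.

Coordinate convention: 0-based, half-open everywhere inside the package.
Hit coordinates always refer to the forward strand of the stored sequence,
whatever the ``strand`` field says.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .exceptions import FormatError

logger = logging.getLogger(__name__)

ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: base order used for PWM rows
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One promoter sequence anchored at its transcription start site.

    ``tss_offset`` is the 0-based position of the TSS within ``bases``; the
    default convention (set by :func:`read_fasta`) places it at the 3' end,
    matching promoter windows extracted upstream of the TSS.
    """

    id: str
    bases: str
    tss_offset: int = 0
    genomic_interval: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r}: empty sequence")
        bad = set(self.bases) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: characters outside ACGTN: {sorted(bad)}"
            )
        if not 0 <= self.tss_offset <= len(self.bases):
            raise ValueError(
                f"sequence {self.id!r}: tss_offset {self.tss_offset} outside "
                f"[0, {len(self.bases)}]"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Pwm:
    """Position weight matrix as raw per-position base counts (4 x L)."""

    matrix_id: str
    counts: np.ndarray  # shape (4, L), rows in order A, C, G, T

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.matrix_id}: counts must be 4 x L")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.matrix_id}: negative counts")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError(f"{self.matrix_id}: column with all-zero counts")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class TfbsHit:
    """One predicted binding-site interval for one matrix on one sequence."""

    sequence_id: str
    matrix_id: str
    start: int
    end: int
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"hit {self.sequence_id}/{self.matrix_id}: start {self.start} "
                f">= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        """Midpoint position: start + floor(length/2), in sequence coordinates."""
        return self.start + (self.end - self.start) // 2


def sort_hits(hits: Iterable[TfbsHit]) -> list[TfbsHit]:
    """Deterministic canonical hit ordering."""
    return sorted(
        hits, key=lambda h: (h.sequence_id, h.start, h.end, h.matrix_id, h.strand)
    )


# ---------------------------------------------------------------------------
# FASTA and sidecar tables
# ---------------------------------------------------------------------------

def read_tss_table(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV ``sequence_id <tab> tss_offset``."""
    table: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        try:
            table[parts[0]] = int(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer tss_offset") from exc
    return table


def read_interval_table(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Read a BED-like sidecar: ``chrom <tab> start <tab> end <tab> sequence_id``."""
    table: dict[str, tuple[str, int, int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        chrom, start, end, seq_id = parts
        table[seq_id] = (chrom, int(start), int(end))
    return table


def read_fasta(
    path: str | Path,
    tss_table: Optional[dict[str, int]] = None,
    downstream_extent: Optional[int] = None,
    intervals: Optional[dict[str, tuple[str, int, int]]] = None,
) -> list[SequenceRecord]:
    """Read promoter sequences from FASTA.

    The TSS offset defaults to the sequence length (promoter window taken
    upstream of the TSS).  ``downstream_extent`` moves it to
    ``length - downstream_extent`` globally (e.g. 100 for windows spanning
    500 bp upstream to 100 bp downstream); ``tss_table`` overrides per record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        bases = str(entry.seq).upper().replace("U", "T")
        tss = len(bases)
        if downstream_extent is not None:
            tss = len(bases) - downstream_extent
        if tss_table is not None and entry.id in tss_table:
            tss = tss_table[entry.id]
        try:
            rec = SequenceRecord(
                id=entry.id,
                bases=bases,
                tss_offset=tss,
                genomic_interval=intervals.get(entry.id) if intervals else None,
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        records.append(rec)
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), 70):
                fh.write(rec.bases[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# TRANSFAC-style matrix flat files
# ---------------------------------------------------------------------------

def read_transfac_matrices(path: str | Path) -> list[Pwm]:
    """Parse TRANSFAC-style flat-file matrix blocks (ID / P0 rows / ``//``).

    Only the count table is used; accession lines, consensus letters and any
    other annotation are ignored.
    """
    pwms: list[Pwm] = []
    block_id: Optional[str] = None
    in_table = False
    columns: list[list[float]] = []

    def finish(lineno: int) -> None:
        nonlocal block_id, in_table, columns
        if block_id is None:
            return
        if not in_table:
            raise FormatError(
                f"{path}:{lineno}: matrix block {block_id!r} missing P0/PO header"
            )
        if not columns:
            raise FormatError(f"{path}:{lineno}: matrix block {block_id!r} empty")
        counts = np.array(columns, dtype=float).T  # (4, L)
        try:
            pwms.append(Pwm(matrix_id=block_id, counts=counts))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        block_id, in_table, columns = None, False, []

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip()
        if not line:
            continue
        tag, _, rest = line.partition(" ")
        if tag == "ID":
            if block_id is not None:
                finish(lineno)
            block_id = rest.strip().split()[0] if rest.strip() else None
            if not block_id:
                raise FormatError(f"{path}:{lineno}: ID line without identifier")
        elif tag in ("P0", "PO"):
            in_table = True
        elif tag == "//":
            finish(lineno)
        elif block_id is not None and in_table and tag[:1].isdigit():
            fields = line.split()
            if len(fields) < 5:
                raise FormatError(
                    f"{path}:{lineno}: matrix row needs 4 count columns"
                )
            try:
                columns.append([float(x) for x in fields[1:5]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric count") from exc
        # other tags (NA, DE, BF, CC, XX, ...) are annotation; skip
    if block_id is not None:
        finish(lineno)
    return pwms


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

_HIT_HEADER = "sequence_id\tmatrix_id\tstart\tend\tstrand\tscore"
_HIT_COORD_COMMENT = "# coordinates: 0-based, half-open"


def read_hits(
    path: str | Path, known_ids: Optional[set[str]] = None
) -> list[TfbsHit]:
    """Read a binding-site hit table (TSV, 0-based half-open coordinates)."""
    hits: list[TfbsHit] = []
    header_seen = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            if line.split("\t") != _HIT_HEADER.split("\t"):
                raise FormatError(f"{path}:{lineno}: unexpected header {line!r}")
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise FormatError(f"{path}:{lineno}: expected 6 columns")
        seq_id, matrix_id, start, end, strand, score = parts
        try:
            hit = TfbsHit(seq_id, matrix_id, int(start), int(end), strand,
                          float(score))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        hits.append(hit)
    if not header_seen and hits:
        raise FormatError(f"{path}: missing header")
    if known_ids is not None:
        unknown = {h.sequence_id for h in hits} - known_ids
        if unknown:
            logger.warning("hit table references unknown sequence ids: %s",
                           sorted(unknown))
    return hits


def write_hits(hits: Sequence[TfbsHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_HIT_COORD_COMMENT + "\n")
        fh.write(_HIT_HEADER + "\n")
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.matrix_id}\t{h.start}\t{h.end}\t"
                f"{h.strand}\t{h.score:g}\n"
            )


# ---------------------------------------------------------------------------
# Stand-in PWM scanner
# ---------------------------------------------------------------------------

def estimate_background(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Base frequencies (A,C,G,T) pooled over a sequence set; N is ignored."""
    counts = np.zeros(4)
    for rec in records:
        for b, i in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
            counts[i] += rec.bases.count(b)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def _logodds(pwm: Pwm, background: np.ndarray) -> np.ndarray:
    """Per-position log2-odds with pseudocount 0.01 x column total per cell."""
    col_tot = pwm.counts.sum(axis=0, keepdims=True)
    pseudo = 0.01 * col_tot
    probs = (pwm.counts + pseudo) / (col_tot + 4 * pseudo)
    return np.log2(probs / background[:, None])


def _encode(bases: str) -> np.ndarray:
    return np.frombuffer(
        bases.encode("ascii").translate(
            bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))
        ),
        dtype=np.uint8,
    ).astype(np.intp)


def scan_sequence(
    record: SequenceRecord,
    pwm: Pwm,
    min_score: float = 0.85,
    background: Optional[np.ndarray] = None,
) -> list[TfbsHit]:
    """Scan one sequence (both strands) with a log-odds PWM score.

    The window score is min-max normalized so the best achievable window
    scores 1.0 and the worst 0.0; windows containing N never produce hits.
    This is a plain, documented scorer: the pipeline only consumes hit
    positions, and hit tables from any external scanner can be supplied
    instead.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must lie in [0, 1]")
    L = pwm.length
    n = len(record.bases)
    if n < L:
        return []
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    W = _logodds(pwm, bg)
    s_max = W.max(axis=0).sum()
    s_min = W.min(axis=0).sum()
    span = s_max - s_min
    codes = _encode(record.bases)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = ~(windows == 4).any(axis=1)
    pos_idx = np.arange(L)
    hits: list[TfbsHit] = []
    for strand, Ws in (("+", W), ("-", W[::-1, ::-1])):
        safe = np.where(windows == 4, 0, windows)
        scores = Ws[safe, pos_idx].sum(axis=1)
        if span > 0:
            norm = (scores - s_min) / span
        else:  # degenerate matrix: every window is simultaneously best/worst
            norm = np.ones_like(scores)
        keep = valid & (norm >= min_score - 1e-12)
        for i in np.nonzero(keep)[0]:
            hits.append(
                TfbsHit(record.id, pwm.matrix_id, int(i), int(i) + L, strand,
                        float(min(norm[i], 1.0)))
            )
    return sort_hits(hits)


def scan_exact(
    record: SequenceRecord, matrix_id: str, consensus: str
) -> list[TfbsHit]:
    """Exact consensus matching on both strands (score fixed at 1.0).

    A palindromic consensus yields two hits per occurrence, one per strand,
    mirroring PWM scanners; the same-type overlap filter collapses them.
    """
    consensus = consensus.upper()
    L = len(consensus)
    hits: list[TfbsHit] = []
    for strand, pat in (("+", consensus), ("-", reverse_complement(consensus))):
        start = record.bases.find(pat)
        while start != -1:
            hits.append(TfbsHit(record.id, matrix_id, start, start + L, strand, 1.0))
            start = record.bases.find(pat, start + 1)
    return sort_hits(hits)


def scan_records(
    records: Sequence[SequenceRecord],
    pwms: Optional[Sequence[Pwm]] = None,
    consensus_motifs: Optional[dict[str, str]] = None,
    min_score: float = 0.85,
) -> list[TfbsHit]:
    """Scan a sequence set with PWMs (log-odds) and/or exact consensus motifs.

    PWM scanning uses background base frequencies estimated from the scanned
    set itself.
    """
    hits: list[TfbsHit] = []
    bg = estimate_background(records) if pwms else None
    for rec in records:
        for pwm in pwms or []:
            hits.extend(scan_sequence(rec, pwm, min_score=min_score, background=bg))
        for mid, consensus in (consensus_motifs or {}).items():
            hits.extend(scan_exact(rec, mid, consensus))
    return sort_hits(hits)


# ---------------------------------------------------------------------------
# Promoter redundancy filter
# ---------------------------------------------------------------------------

def deduplicate_promoters(
    records: Sequence[SequenceRecord],
) -> list[SequenceRecord]:
    """Drop every promoter whose genomic interval overlaps another's.

    Both members of an overlapping pair are removed (intervals are half-open,
    so touching windows do not overlap).  Records without an interval pass
    through with a warning.
    """
    flagged: set[str] = set()
    by_chrom: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        if rec.genomic_interval is None:
            logger.warning("record %s has no genomic interval; kept as-is", rec.id)
            continue
        by_chrom.setdefault(rec.genomic_interval[0], []).append(rec)
    for chrom_recs in by_chrom.values():
        chrom_recs.sort(key=lambda r: (r.genomic_interval[1], r.genomic_interval[2]))
        active: list[tuple[int, str]] = []  # heap of (end, id)
        for rec in chrom_recs:
            _, start, end = rec.genomic_interval
            while active and active[0][0] <= start:
                heapq.heappop(active)
            if active:  # every remaining active interval overlaps this one
                flagged.add(rec.id)
                flagged.update(rid for _, rid in active)
            heapq.heappush(active, (end, rec.id))
    if flagged:
        logger.info("promoter redundancy filter removed %d sequences", len(flagged))
    return [rec for rec in records if rec.id not in flagged]
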