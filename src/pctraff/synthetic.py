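"""Spike-in benchmark generator with ground truth.

Emulates the positive-control experiment the method is validated on: a set
of promoter-like background sequences (i.i.d. bases at human-genome-like GC
content) into which one designated TFBS pair is planted 2-12 times per
sequence as a tandem motif_a .. motif_b block separated by a short
background spacer, plus a panel of decoy motifs inserted independently
(Poisson counts, uniform positions, no positional coupling).  The decoy
panel plays the role of the remaining motif library in a real scan: its
per-type insertion rates are spread over roughly two orders of magnitude
(panel mean = ``decoy_rate``), mimicking the highly dispersed hit
frequencies of real PWM collections that the Phase-1 column filters are
designed for.

All motif consensus strings here are synthetic stand-ins, not entries of
any proprietary matrix library; the two planted-motif ids follow the
conventional vertebrate naming purely as labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import PlacementError
from .tfbs_io import SequenceRecord, TfbsHit, scan_exact, sort_hits

#: planted pair: IRF-like and E-box-like synthetic consensi (non-palindromic)
DEFAULT_PAIR_MOTIFS: tuple[tuple[str, str], tuple[str, str]] = (
    ("V$IRF1_01", "TTTCACTTTC"),
    ("V$USF_01", "CACGTGAC"),
)

#: (id, consensus, relative insertion rate); relative rates average exactly 1,
#: so per-type rates are decoy_rate * relative.  Short promiscuous motifs get
#: high rates, long specific ones low rates, like a real motif library.
DECOY_PANEL: list[tuple[str, str, float]] = [
    ("D$NRHALF_01", "AGGTCA", 3.0),
    ("D$GATA_01", "GATAAG", 7.0 / 3.0),
    ("D$EBOXCA_01", "CAGGTG", 5.0 / 3.0),
    ("D$AP1_01", "TGACTCA", 1.4),
    ("D$CAAT_01", "GCCAATC", 7.0 / 6.0),
    ("D$TRICH_01", "TTTGTTT", 5.0 / 6.0),
    ("D$OCT_01", "ATGCAAAT", 0.6),
    ("D$MISC_01", "CTTTGTCC", 0.4),
    ("D$CREB_01", "TGACGTCAT", 4.0 / 15.0),
    ("D$SP1_01", "GGGGCGGGG", 1.0 / 6.0),
    ("D$NFKB_01", "GGGACTTTCC", 0.1),
    ("D$MISC_02", "TTCTAGGCAT", 1.0 / 15.0),
]


@dataclass
class SpikeInConfig:
    """Study conditions of the spike-in experiment."""

    n_sequences: int = 200
    seq_length: int = 1000
    gc_content: float = 0.41
    pair_motifs: tuple[tuple[str, str], tuple[str, str]] = DEFAULT_PAIR_MOTIFS
    insertions_min: int = 2
    insertions_max: int = 12
    gap_min: int = 5
    gap_max: int = 20
    n_decoy_motifs: int = 12
    decoy_rate: float = 3.0
    random_strand: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.insertions_min < 0 or self.insertions_max < self.insertions_min:
            raise ValueError("invalid insertion range")
        if self.gap_min < 0 or self.gap_max < self.gap_min:
            raise ValueError("invalid gap range")
        if not 0 <= self.n_decoy_motifs <= len(DECOY_PANEL):
            raise ValueError(
                f"n_decoy_motifs must lie in [0, {len(DECOY_PANEL)}]"
            )

    @property
    def decoys(self) -> list[tuple[str, str, float]]:
        """Selected decoys with absolute per-sequence rates (panel mean = decoy_rate)."""
        panel = DECOY_PANEL[: self.n_decoy_motifs]
        if not panel:
            return []
        mean_rel = sum(r for _, _, r in panel) / len(panel)
        return [(mid, m, self.decoy_rate * r / mean_rel) for mid, m, r in panel]

    def motifs(self) -> dict[str, str]:
        """All motif consensi (planted pair + decoys) keyed by matrix id."""
        out = {mid: m for mid, m in self.pair_motifs}
        out.update({mid: m for mid, m, _ in self.decoys})
        return out


@dataclass
class SpikeInDataset:
    records: list[SequenceRecord]
    pair_truth: pd.DataFrame  # sequence_id, start_a, start_b, gap, strand
    decoy_truth: pd.DataFrame  # sequence_id, matrix_id, start, strand
    config: SpikeInConfig

    @property
    def planted_pair(self) -> tuple[str, str]:
        (a, _), (b, _) = self.config.pair_motifs
        return (a, b) if a <= b else (b, a)

    def scan(self) -> list[TfbsHit]:
        """Exact-consensus scan of the dataset with its own motif panel."""
        hits: list[TfbsHit] = []
        motifs = self.config.motifs()
        for rec in self.records:
            for mid, consensus in motifs.items():
                hits.extend(scan_exact(rec, mid, consensus))
        return sort_hits(hits)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def generate_background(
    cfg: SpikeInConfig, rng: Optional[np.random.Generator] = None
) -> list[SequenceRecord]:
    """i.i.d. background sequences with P(G) + P(C) = gc_content; TSS at 3' end."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    width = len(str(max(cfg.n_sequences, 1)))
    records = []
    for i in range(cfg.n_sequences):
        bases = _random_bases(rng, cfg.seq_length, cfg.gc_content)
        records.append(
            SequenceRecord(
                id=f"seq_{i + 1:0{width}d}",
                bases=bases.tobytes().decode("ascii"),
                tss_offset=cfg.seq_length,
            )
        )
    return records


Occupied = dict[str, list[tuple[int, int]]]


def _place(
    rng: np.random.Generator,
    seq_len: int,
    length: int,
    taken: list[tuple[int, int]],
    max_tries: int = 500,
) -> Optional[int]:
    """Uniform start for an interval of ``length`` avoiding ``taken`` intervals."""
    if seq_len < length:
        return None
    for _ in range(max_tries):
        start = int(rng.integers(0, seq_len - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in taken):
            return start
    return None


def _overwrite(bases: bytearray, start: int, motif: str) -> None:
    bases[start : start + len(motif)] = motif.encode("ascii")


def plant_pairs(
    records: Sequence[SequenceRecord],
    cfg: SpikeInConfig,
    rng: Optional[np.random.Generator] = None,
    occupied: Optional[Occupied] = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Insert the designated pair 2-12 times per sequence at 5-20 bp spacers.

    Each insertion overwrites background with motif_a, ``gap`` untouched
    background bases, then motif_b; the two motif intervals are reserved so
    no later insertion overwrites them.  Sequence length is preserved.
    """
    from .tfbs_io import reverse_complement

    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    (id_a, motif_a), (id_b, motif_b) = cfg.pair_motifs
    la, lb = len(motif_a), len(motif_b)
    out: list[SequenceRecord] = []
    truth_rows = []
    for rec in records:
        taken = occupied.setdefault(rec.id, []) if occupied is not None else []
        bases = bytearray(rec.bases, "ascii")
        k = int(rng.integers(cfg.insertions_min, cfg.insertions_max + 1))
        for _ in range(k):
            gap = int(rng.integers(cfg.gap_min, cfg.gap_max + 1))
            block = la + gap + lb
            start = _place(rng, len(bases), block, taken)
            if start is None:
                raise PlacementError(
                    f"sequence {rec.id}: could not place pair insertion "
                    f"(length {block}) without overlap"
                )
            ma, mb = motif_a, motif_b
            strand = "+"
            if cfg.random_strand and rng.integers(2):
                # insert the reverse-complemented block: b' gap a'
                ma, mb = reverse_complement(motif_b), reverse_complement(motif_a)
                strand = "-"
            _overwrite(bases, start, ma)
            _overwrite(bases, start + len(ma) + gap, mb)
            taken.append((start, start + len(ma)))
            taken.append((start + len(ma) + gap, start + block))
            truth_rows.append(
                {
                    "sequence_id": rec.id,
                    "start_a": start,
                    "start_b": start + len(ma) + gap,
                    "gap": gap,
                    "strand": strand,
                }
            )
        out.append(
            SequenceRecord(rec.id, bases.decode("ascii"), rec.tss_offset,
                           rec.genomic_interval)
        )
    truth = pd.DataFrame(
        truth_rows, columns=["sequence_id", "start_a", "start_b", "gap", "strand"]
    )
    return out, truth


def plant_decoys(
    records: Sequence[SequenceRecord],
    cfg: SpikeInConfig,
    rng: Optional[np.random.Generator] = None,
    occupied: Optional[Occupied] = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Insert each decoy motif independently (Poisson counts, uniform positions)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    decoys = cfg.decoys
    out: list[SequenceRecord] = []
    truth_rows = []
    for rec in records:
        taken = occupied.setdefault(rec.id, []) if occupied is not None else []
        bases = bytearray(rec.bases, "ascii")
        for mid, motif, rate in decoys:
            for _ in range(int(rng.poisson(rate))):
                start = _place(rng, len(bases), len(motif), taken)
                if start is None:
                    raise PlacementError(
                        f"sequence {rec.id}: could not place decoy {mid} "
                        "without overlap"
                    )
                _overwrite(bases, start, motif)
                taken.append((start, start + len(motif)))
                truth_rows.append(
                    {"sequence_id": rec.id, "matrix_id": mid, "start": start,
                     "strand": "+"}
                )
        out.append(
            SequenceRecord(rec.id, bases.decode("ascii"), rec.tss_offset,
                           rec.genomic_interval)
        )
    truth = pd.DataFrame(
        truth_rows, columns=["sequence_id", "matrix_id", "start", "strand"]
    )
    return out, truth


def generate_dataset(cfg: SpikeInConfig, plant_pair: bool = True) -> SpikeInDataset:
    """Full spike-in dataset: background + planted pair + decoys, one seed.

    ``plant_pair=False`` yields a decoy-only negative control.
    """
    rng = np.random.default_rng(cfg.seed)
    records = generate_background(cfg, rng)
    occupied: Occupied = {}
    if plant_pair:
        records, pair_truth = plant_pairs(records, cfg, rng, occupied)
    else:
        pair_truth = pd.DataFrame(
            columns=["sequence_id", "start_a", "start_b", "gap", "strand"]
        )
    records, decoy_truth = plant_decoys(records, cfg, rng, occupied)
    return SpikeInDataset(
        records=records, pair_truth=pair_truth, decoy_truth=decoy_truth, config=cfg
    )
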