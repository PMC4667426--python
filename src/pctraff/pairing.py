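"""Phase 4: distance-constrained pair construction.

Two binding sites form a candidate pair when the absolute distance between
their midpoints lies within [d_min, d_max]; sites of different types may
overlap by at most ``max_overlap`` bases, sites of the same type may not
overlap at all.  To keep homotypic clusters from inflating counts, a site
participates in at most one counted pair *per pair type*: candidates are
scanned 5'->3' (by left midpoint, then right midpoint) and counted greedily
whenever neither site has already been used for that pair type.  The same
site may still be counted once for each other pair type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .exceptions import PcTraffError
from .tfbs_io import TfbsHit

Pair = tuple[str, str]


def midpoint(hit: TfbsHit) -> int:
    """Midpoint of a hit: start + floor(length/2)."""
    return hit.midpoint


def pair_distance(hit_a: TfbsHit, hit_b: TfbsHit) -> int:
    """Absolute distance between the midpoints of two same-sequence hits."""
    if hit_a.sequence_id != hit_b.sequence_id:
        raise PcTraffError(
            f"pair distance across sequences {hit_a.sequence_id!r} / "
            f"{hit_b.sequence_id!r}"
        )
    return abs(hit_a.midpoint - hit_b.midpoint)


def canonical_pair(type_a: str, type_b: str) -> Pair:
    """Unordered pair key, lexicographically canonicalized."""
    return (type_a, type_b) if type_a <= type_b else (type_b, type_a)


def _overlap(a: TfbsHit, b: TfbsHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class PairInstance:
    """One counted co-occurrence of two binding sites."""

    sequence_id: str
    type_a: str
    type_b: str
    hit_a: TfbsHit
    hit_b: TfbsHit
    distance: int


@dataclass
class PairCountTable:
    """Per-sequence and pooled counts of unordered pair instances."""

    per_sequence: dict[tuple[str, Pair], int]
    n_s: dict[str, int]  # total pair instances per sequence (N_s)
    pooled: dict[Pair, int]  # F(a, b)
    instances: list[PairInstance] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.pooled.values())

    def instances_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sequence_id": pi.sequence_id,
                "type_a": pi.type_a,
                "type_b": pi.type_b,
                "start_a": pi.hit_a.start,
                "end_a": pi.hit_a.end,
                "start_b": pi.hit_b.start,
                "end_b": pi.hit_b.end,
                "distance": pi.distance,
            }
            for pi in self.instances
        ]
        return pd.DataFrame(
            rows,
            columns=["sequence_id", "type_a", "type_b", "start_a", "end_a",
                     "start_b", "end_b", "distance"],
        )


def enumerate_pairs(
    hits: Iterable[TfbsHit],
    d_min: int = 5,
    d_max: int = 20,
    max_overlap: int = 4,
    sequence_ids: Optional[Sequence[str]] = None,
    keep_instances: bool = False,
) -> PairCountTable:
    """Count distance-constrained pairs with greedy disjoint homotypic matching.

    ``sequence_ids`` fixes the sequence universe for the N_s table (sequences
    without any counted pair keep N_s = 0); by default it is the set of
    sequences carrying hits.  Counting is invariant to input hit order.
    """
    if d_min < 0 or d_max < d_min or max_overlap < 0:
        raise PcTraffError("require 0 <= d_min <= d_max and max_overlap >= 0")

    by_seq: dict[str, list[TfbsHit]] = {}
    for h in hits:
        by_seq.setdefault(h.sequence_id, []).append(h)
    if sequence_ids is None:
        sequence_ids = sorted(by_seq)

    per_sequence: dict[tuple[str, Pair], int] = {}
    n_s: dict[str, int] = {sid: 0 for sid in sequence_ids}
    pooled: dict[Pair, int] = {}
    instances: list[PairInstance] = []

    for sid in sorted(by_seq):
        seq_hits = sorted(
            by_seq[sid], key=lambda h: (h.midpoint, h.start, h.matrix_id, h.strand)
        )
        # candidates per pair type, generated in (left midpoint, right midpoint)
        # order by construction of the double loop
        candidates: dict[Pair, list[tuple[int, int]]] = {}
        for i in range(len(seq_hits)):
            hi = seq_hits[i]
            for j in range(i + 1, len(seq_hits)):
                hj = seq_hits[j]
                d = hj.midpoint - hi.midpoint
                if d > d_max:
                    break  # hits sorted by midpoint
                if d < d_min:
                    continue
                ov = _overlap(hi, hj)
                if hi.matrix_id == hj.matrix_id:
                    if ov > 0:
                        continue  # same-type overlaps are never paired
                elif ov > max_overlap:
                    continue
                pair = canonical_pair(hi.matrix_id, hj.matrix_id)
                candidates.setdefault(pair, []).append((i, j))
        for pair in sorted(candidates):
            used: set[int] = set()
            for i, j in candidates[pair]:
                if i in used or j in used:
                    continue
                used.update((i, j))
                key = (sid, pair)
                per_sequence[key] = per_sequence.get(key, 0) + 1
                n_s[sid] = n_s.get(sid, 0) + 1
                pooled[pair] = pooled.get(pair, 0) + 1
                if keep_instances:
                    ha, hb = seq_hits[i], seq_hits[j]
                    if not (ha.matrix_id, hb.matrix_id) == pair:
                        ha, hb = hb, ha
                    instances.append(
                        PairInstance(sid, pair[0], pair[1], ha, hb,
                                     pair_distance(ha, hb))
                    )

    return PairCountTable(
        per_sequence=per_sequence, n_s=n_s, pooled=pooled, instances=instances
    )
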