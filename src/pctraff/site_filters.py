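"""Phase 3: resolve overlapping same-type binding sites.

PWM scanning (palindromic motifs, matrices wider than the true site) can
predict overlapping sites of the same type, which would inflate that type's
pair counts.  Within each (sequence, type) group, overlapping hits are
clustered by transitive interval overlap and exactly one survivor is kept
per cluster: the hit whose midpoint lies nearest the TSS, functional sites
tending to sit close to it.  Overlaps between *different* types are left
alone (a small inter-type overlap is legitimate and handled in pairing).
"""

from __future__ import annotations

from typing import Sequence

from .tfbs_io import SequenceRecord, TfbsHit, sort_hits


def _survivor(cluster: list[TfbsHit], tss: int) -> TfbsHit:
    # nearest midpoint to TSS; ties: smaller start, then '+' strand first
    return min(
        cluster,
        key=lambda h: (abs(h.midpoint - tss), h.start, 0 if h.strand == "+" else 1),
    )


def resolve_same_type_overlaps(
    hits: Sequence[TfbsHit], records: Sequence[SequenceRecord]
) -> list[TfbsHit]:
    """Keep one hit per same-type overlap cluster, the one closest to the TSS."""
    tss = {rec.id: rec.tss_offset for rec in records}
    groups: dict[tuple[str, str], list[TfbsHit]] = {}
    for h in hits:
        groups.setdefault((h.sequence_id, h.matrix_id), []).append(h)

    kept: list[TfbsHit] = []
    for (seq_id, _), group in groups.items():
        group.sort(key=lambda h: (h.start, h.end))
        cluster: list[TfbsHit] = []
        cluster_end = -1
        for h in group:
            if cluster and h.start >= cluster_end:  # half-open: touching is disjoint
                kept.append(_survivor(cluster, tss[seq_id]))
                cluster = []
                cluster_end = -1
            cluster.append(h)
            cluster_end = max(cluster_end, h.end)
        if cluster:
            kept.append(_survivor(cluster, tss[seq_id]))
    return sort_hits(kept)
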