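"""Phase 2: sequence-by-TFBS pointwise mutual information.

For the filtered TFBS-sequence matrix with total count T = sum f_ij,

    PMI(s_i; t_j) = log2( p(s_i, t_j) / (p(s_i) * p(t_j)) )

with p(s_i, t_j) = f_ij / T and marginals p(s_i) = rowsum_i / T,
p(t_j) = colsum_j / T.  A positive score marks type j as occurring in
sequence i more often than expected under independence; only such
"important" (sequence, type) combinations are carried into pairing.
Cells with f_ij = 0 have no finite PMI and are excluded outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .exceptions import EmptyMatrixError
from .tfbs_io import TfbsHit
from .tsm import TsmMatrix


@dataclass
class ImportanceTable:
    """PMI per (sequence, type) cell and the retained important sets."""

    pmi: dict[tuple[str, str], float]
    important: dict[str, frozenset[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sequence_id": s, "matrix_id": t, "pmi": v}
            for (s, t), v in sorted(self.pmi.items())
        ]
        return pd.DataFrame(rows, columns=["sequence_id", "matrix_id", "pmi"])


def sequence_tfbs_pmi(tsm: TsmMatrix) -> ImportanceTable:
    """Compute PMI(s_i; t_j) for every non-zero cell of the matrix."""
    f = tsm.table
    total = int(f.to_numpy().sum())
    if total == 0:
        raise EmptyMatrixError("empty matrix")
    row_sums = f.sum(axis=1)
    col_sums = f.sum(axis=0)
    pmi: dict[tuple[str, str], float] = {}
    for i in f.index:
        ri = int(row_sums[i])
        if ri == 0:
            continue
        for j in f.columns:
            fij = int(f.at[i, j])
            if fij == 0:
                continue
            # log2( (fij/T) / ((ri/T)(cj/T)) ) = log2(fij * T / (ri * cj))
            pmi[(i, j)] = math.log2(fij * total / (ri * int(col_sums[j])))
    return ImportanceTable(pmi=pmi)


def select_important(table: ImportanceTable) -> ImportanceTable:
    """Retain, per sequence, the types with strictly positive PMI."""
    important: dict[str, set[str]] = {}
    for (s, t), v in table.pmi.items():
        if v > 0:
            important.setdefault(s, set()).add(t)
    return ImportanceTable(
        pmi=dict(table.pmi),
        important={s: frozenset(ts) for s, ts in important.items()},
    )


def restrict_hits(
    hits: Sequence[TfbsHit], table: ImportanceTable
) -> list[TfbsHit]:
    """Keep exactly the hits whose (sequence, type) is important.

    Hits of types removed by the Phase-1 column filters are dropped too,
    since such cells never acquire a PMI value.
    """
    empty: frozenset[str] = frozenset()
    return [
        h for h in hits if h.matrix_id in table.important.get(h.sequence_id, empty)
    ]
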