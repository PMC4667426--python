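"""Phase 1: the TFBS-sequence matrix and its two column filters.

The matrix ``M`` holds f_ij, the number of binding sites of type j predicted
in sequence i.  Two single-pass column filters remove (i) highly
over-represented types, whose column sum exceeds three population standard
deviations of the column-sum vector, and (ii) sparse types, with strictly
more zero entries than the column average.  Both thresholds are computed on
the filter's *input* matrix and not recomputed after removals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import PcTraffError
from .tfbs_io import SequenceRecord, TfbsHit

logger = logging.getLogger(__name__)


@dataclass
class TsmMatrix:
    """TFBS-sequence frequency matrix (rows: sequences, columns: matrix ids)."""

    table: pd.DataFrame  # integer frequencies f_ij
    sigma: Optional[float] = None  # column-sum population SD, set by the 3-sigma filter

    @property
    def row_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.table.columns)

    @property
    def f(self) -> np.ndarray:
        return self.table.to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sequence_id")


def build_tsm(
    hits: Sequence[TfbsHit], records: Sequence[SequenceRecord]
) -> TsmMatrix:
    """Count hits of each type per sequence.

    Rows follow record order; columns are sorted by matrix id for
    determinism.  A hit referencing an unknown sequence is an error.
    """
    row_ids = [rec.id for rec in records]
    known = set(row_ids)
    col_ids = sorted({h.matrix_id for h in hits})
    table = pd.DataFrame(0, index=row_ids, columns=col_ids, dtype=int)
    for h in hits:
        if h.sequence_id not in known:
            raise PcTraffError(
                f"hit references unknown sequence {h.sequence_id!r}"
            )
        table.loc[h.sequence_id, h.matrix_id] += 1
    if len(col_ids):
        empty_rows = table.index[table.sum(axis=1) == 0]
        if len(empty_rows):
            logger.warning(
                "%d sequences have no hits (all-zero rows): %s%s",
                len(empty_rows), list(empty_rows[:5]),
                "..." if len(empty_rows) > 5 else "",
            )
    return TsmMatrix(table=table)


def filter_overrepresented(tsm: TsmMatrix) -> TsmMatrix:
    """Remove columns whose sum exceeds 3 x (population SD of column sums).

    sigma is computed once on the input matrix; sigma = 0 (all column sums
    equal) disables the filter rather than removing every column.
    """
    if tsm.table.shape[1] == 0:
        raise PcTraffError("matrix has no columns")
    col_sums = tsm.table.sum(axis=0)
    sigma = float(np.std(col_sums.to_numpy(), ddof=0))
    if sigma == 0.0:
        logger.info("over-representation filter: sigma = 0, no columns removed")
        return TsmMatrix(table=tsm.table.copy(), sigma=sigma)
    removed = col_sums.index[col_sums > 3.0 * sigma]
    if len(removed):
        logger.info(
            "over-representation filter (3*sigma = %.3f) removed %d columns: %s",
            3.0 * sigma, len(removed), list(removed),
        )
    return TsmMatrix(table=tsm.table.drop(columns=removed), sigma=sigma)


def filter_sparse(tsm: TsmMatrix) -> TsmMatrix:
    """Remove columns with strictly more zero entries than the column average."""
    if tsm.table.shape[1] == 0:
        raise PcTraffError("matrix has no columns")
    zeros = (tsm.table == 0).sum(axis=0)
    zbar = float(zeros.to_numpy().mean())
    removed = zeros.index[zeros > zbar]
    if len(removed):
        logger.info(
            "sparsity filter (mean zero count %.3f) removed %d columns: %s",
            zbar, len(removed), list(removed),
        )
    return TsmMatrix(table=tsm.table.drop(columns=removed), sigma=tsm.sigma)
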