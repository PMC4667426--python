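import pytest

from pctraff.pairing import PairCountTable
from pctraff.tfbs_io import SequenceRecord, TfbsHit


def make_hit(seq="s1", mat="A", start=0, end=6, strand="+", score=1.0):
    return TfbsHit(seq, mat, start, end, strand, score)


def make_record(seq_id="s1", bases="ACGT" * 50, tss=None):
    return SequenceRecord(seq_id, bases, len(bases) if tss is None else tss)


@pytest.fixture
def micro_counts():
    """Hand-checkable pair-count table: s1 carries (A,B)x2 and (A,C)x1,
    s2 carries (A,B)x1."""
    return PairCountTable(
        per_sequence={
            ("s1", ("A", "B")): 2,
            ("s1", ("A", "C")): 1,
            ("s2", ("A", "B")): 1,
        },
        n_s={"s1": 3, "s2": 1},
        pooled={("A", "B"): 3, ("A", "C"): 1},
    )


@pytest.fixture
def micro_pipeline_inputs():
    """Sequences and engineered hits that, with column/importance filters
    off, pair up exactly as the micro count table above."""
    records = [
        SequenceRecord("s1", "A" * 200, 200),
        SequenceRecord("s2", "A" * 200, 200),
    ]
    hits = [
        # s1: two A-B pairs at midpoint distance 10, one A-C pair
        make_hit("s1", "A", 10, 16), make_hit("s1", "B", 20, 26),
        make_hit("s1", "A", 40, 46), make_hit("s1", "B", 50, 56),
        make_hit("s1", "A", 80, 86), make_hit("s1", "C", 90, 96),
        # s2: one A-B pair
        make_hit("s2", "A", 10, 16), make_hit("s2", "B", 20, 26),
    ]
    return records, hits
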