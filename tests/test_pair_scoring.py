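import math
import statistics

import numpy as np
import pytest

from pctraff.exceptions import InsufficientPairsError, NoPairsError, PcTraffError
from pctraff.pair_scoring import (
    apc_correct,
    cumulative_weighted_pmi,
    pair_pmi,
    pair_probabilities,
    score_pairs,
    sequence_weights,
    zscores,
)
from pctraff.pairing import PairCountTable

from _oracle import pair_scores_oracle


class TestPairProbabilities:
    def test_slot_marginals(self, micro_counts):
        p_joint, p_marg, total = pair_probabilities(micro_counts)
        assert total == 4
        assert p_joint[("A", "B")] == pytest.approx(0.75)
        assert p_marg == pytest.approx({"A": 0.5, "B": 0.375, "C": 0.125})

    def test_marginals_sum_to_one(self, micro_counts):
        _, p_marg, _ = pair_probabilities(micro_counts)
        assert sum(p_marg.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_homotypic_pair(self):
        counts = PairCountTable(
            per_sequence={("s1", ("A", "A")): 1}, n_s={"s1": 1},
            pooled={("A", "A"): 1},
        )
        p_joint, p_marg, _ = pair_probabilities(counts)
        assert p_joint[("A", "A")] == 1.0
        assert p_marg["A"] == 1.0

    def test_empty_counts_rejected(self):
        empty = PairCountTable(per_sequence={}, n_s={}, pooled={})
        with pytest.raises(NoPairsError, match="no pairs"):
            pair_probabilities(empty)


class TestPairPmi:
    def test_worked_values(self, micro_counts):
        p_joint, p_marg, _ = pair_probabilities(micro_counts)
        pmi = pair_pmi(p_joint, p_marg)
        assert pmi[("A", "B")] == pytest.approx(2.0, abs=1e-12)
        assert pmi[("A", "C")] == pytest.approx(2.0, abs=1e-12)

    def test_single_heterotypic_pair_forced_value(self):
        counts = PairCountTable(
            per_sequence={("s1", ("A", "B")): 1}, n_s={"s1": 1},
            pooled={("A", "B"): 1},
        )
        p_joint, p_marg, _ = pair_probabilities(counts)
        assert pair_pmi(p_joint, p_marg)[("A", "B")] == pytest.approx(2.0)


class TestSequenceWeights:
    def test_proportional_to_pair_totals(self, micro_counts):
        assert sequence_weights(micro_counts) == pytest.approx(
            {"s1": 0.75, "s2": 0.25}
        )

    def test_zero_pair_sequences_get_zero_weight(self):
        counts = PairCountTable(
            per_sequence={("s1", ("A", "B")): 2}, n_s={"s1": 2, "s2": 0},
            pooled={("A", "B"): 2},
        )
        w = sequence_weights(counts)
        assert w == pytest.approx({"s1": 1.0, "s2": 0.0})
        assert sum(w.values()) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        counts = PairCountTable(per_sequence={}, n_s={"s1": 0}, pooled={})
        with pytest.raises(NoPairsError):
            sequence_weights(counts)


class TestCumulativeWeightedPmi:
    def test_micro_fixture_values(self, micro_counts):
        p_joint, p_marg, _ = pair_probabilities(micro_counts)
        pmi = pair_pmi(p_joint, p_marg)
        w = sequence_weights(micro_counts)
        pc = cumulative_weighted_pmi(micro_counts, p_joint, pmi, w)
        assert pc[("A", "B")] == pytest.approx(1.5, abs=1e-12)
        assert pc[("A", "C")] == pytest.approx(0.375, abs=1e-12)

    def test_pair_in_every_sequence_keeps_full_weight(self):
        counts = PairCountTable(
            per_sequence={("s1", ("A", "B")): 1, ("s2", ("A", "B")): 3},
            n_s={"s1": 1, "s2": 3},
            pooled={("A", "B"): 4},
        )
        p_joint, p_marg, _ = pair_probabilities(counts)
        pmi = pair_pmi(p_joint, p_marg)
        pc = cumulative_weighted_pmi(counts, p_joint, pmi,
                                     sequence_weights(counts))
        assert pc[("A", "B")] == pytest.approx(p_joint[("A", "B")] * pmi[("A", "B")])


class TestApcCorrection:
    def test_micro_fixture_hand_values(self):
        pmi_pc = {("A", "B"): 1.5, ("A", "C"): 0.375}
        apc, corrected, means, overall = apc_correct(pmi_pc)
        assert means == pytest.approx(
            {"A": 0.9375, "B": 0.75, "C": 0.1875}, abs=1e-12
        )
        assert overall == pytest.approx(0.625, abs=1e-12)
        assert apc[("A", "B")] == pytest.approx(1.125, abs=1e-12)
        assert corrected[("A", "B")] == pytest.approx(0.375, abs=1e-12)
        assert corrected[("A", "C")] == pytest.approx(0.09375, abs=1e-12)
        assert corrected[("B", "C")] == pytest.approx(-0.225, abs=1e-12)

    def test_uniform_structure_fully_removed(self):
        pmi_pc = {("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5}
        _, corrected, _, _ = apc_correct(pmi_pc)
        assert all(v == 0.0 for v in corrected.values())

    def test_two_types_forced_zero(self):
        _, corrected, _, _ = apc_correct({("A", "B"): 0.7})
        assert corrected[("A", "B")] == 0.0

    def test_single_type_rejected(self):
        with pytest.raises(PcTraffError):
            apc_correct({("A", "A"): 1.0})

    def test_degenerate_zero_mean_gives_zero_apc(self):
        apc, corrected, _, overall = apc_correct({("A", "B"): 0.0, ("A", "C"): 0.0})
        assert overall == 0.0
        assert all(v == 0.0 for v in apc.values())


class TestZscores:
    def test_micro_fixture_z(self):
        corrected = {("A", "B"): 0.375, ("A", "C"): 0.09375, ("B", "C"): -0.225}
        z, sig = zscores(corrected, n_observed=2)
        expected = (0.375 - 0.08125) / statistics.stdev(corrected.values())
        assert z[("A", "B")] == pytest.approx(expected, abs=1e-12)
        assert not any(sig.values())

    def test_constant_corrected_scores_nothing_significant(self):
        z, sig = zscores({("A", "B"): 0.2, ("A", "C"): 0.2}, n_observed=2)
        assert all(v == 0.0 for v in z.values())
        assert not any(sig.values())

    def test_location_invariance(self):
        base = {("A", "B"): 0.3, ("A", "C"): -0.1, ("B", "C"): 0.05}
        shifted = {k: v + 5.0 for k, v in base.items()}
        z1, _ = zscores(base, n_observed=3)
        z2, _ = zscores(shifted, n_observed=3)
        for k in base:
            assert z1[k] == pytest.approx(z2[k], abs=1e-9)

    def test_too_few_observed_pairs_rejected(self):
        with pytest.raises(InsufficientPairsError):
            zscores({("A", "B"): 0.1}, n_observed=1)


class TestScorePairs:
    def test_micro_fixture_table(self, micro_counts):
        table = score_pairs(micro_counts)
        row = table.row("A", "B")
        assert row.F == 3
        assert row.pmi == pytest.approx(2.0, abs=1e-9)
        assert row.pmi_pc == pytest.approx(1.5, abs=1e-9)
        assert row.apc == pytest.approx(1.125, abs=1e-9)
        assert row.pmi_pc_apc == pytest.approx(0.375, abs=1e-9)
        assert table.rank("A", "B") == 1
        # symmetry: lookup order does not matter
        assert table.zscore("B", "A") == table.zscore("A", "B")

    def test_unobserved_slot_carries_no_pmi_but_is_scored(self, micro_counts):
        row = score_pairs(micro_counts).row("B", "C")
        assert row.F == 0
        assert math.isnan(row.pmi)
        assert row.pmi_pc == 0.0
        assert row.pmi_pc_apc == pytest.approx(-0.225, abs=1e-9)

    def test_matches_rational_oracle_on_random_instances(self):
        rng = np.random.default_rng(41)
        checked = 0
        while checked < 50:
            counts = random_counts(rng)
            if counts is None:
                continue
            checked += 1
            table = score_pairs(counts)
            expected = pair_scores_oracle(counts.per_sequence)
            for pair, v in expected["corrected"].items():
                row = table.row(*pair)
                assert row.pmi_pc_apc == pytest.approx(v, abs=1e-9)
                assert row.zscore == pytest.approx(expected["zscore"][pair], abs=1e-9)


def random_counts(rng, max_seqs=5, max_types=6, max_instances=30):
    """Random small pair-count instance, or None when degenerate."""
    m = int(rng.integers(1, max_seqs + 1))
    n = int(rng.integers(2, max_types + 1))
    types = [chr(ord("A") + i) for i in range(n)]
    n_inst = int(rng.integers(2, max_instances + 1))
    per_sequence = {}
    for _ in range(n_inst):
        s = f"s{int(rng.integers(1, m + 1))}"
        a, b = rng.choice(types, size=2)
        pair = (a, b) if a <= b else (b, a)
        per_sequence[(s, pair)] = per_sequence.get((s, pair), 0) + 1
    pooled = {}
    n_s = {}
    for (s, pair), c in per_sequence.items():
        pooled[pair] = pooled.get(pair, 0) + c
        n_s[s] = n_s.get(s, 0) + c
    if len(pooled) < 2 or len({t for p in pooled for t in p}) < 2:
        return None
    return PairCountTable(per_sequence=per_sequence, n_s=n_s, pooled=pooled)
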