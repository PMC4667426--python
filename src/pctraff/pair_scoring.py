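"""Phases 5-6: pair PMI, weighted cumulative PMI, APC correction, z-scores.

Probabilities are derived from pooled pair-instance counts.  With
F(a,b) the pooled count of the unordered pair (a,b) and T their total,

    p(t_a, t_b) = F(a,b) / T
    p(t_a)      = C(a) / (2T),   C(a) = sum_{b != a} F(a,b) + 2 F(a,a)

i.e. marginals count pair-slot occupancy, so sum_a p(t_a) = 1 and the pair
PMI reduces to the standard bigram form

    PMI(t_a; t_b) = log2( p(t_a,t_b) / (p(t_a) p(t_b)) ).

Each pair's PMI is damped by its joint probability and by the weights of
the sequences it occurs in (w_s = N_s / sum N_s), giving the weighted
cumulative score

    PMI_pc(a,b) = [sum over sequences s containing (a,b) of w_s] * p(a,b) * PMI(a,b).

The average product correction then subtracts the background expected from
each type's mean score,

    APC(a,b) = mean_a * mean_b / overall_mean,
    corrected(a,b) = PMI_pc(a,b) - APC(a,b),

where mean_a = 1/(n-1) * sum over all x = 1..n of PMI_pc(a,x) -- the sum
includes the self term when the homotypic pair (a,a) was observed, with
unobserved pairs contributing 0 -- and overall_mean averages PMI_pc over
every scored pair (all n(n-1)/2 heterotypic type slots plus observed
homotypic pairs).  Homotypic pairs receive APC(a,a) = mean_a^2 / overall_mean.  Corrected scores over the full scored
universe (every heterotypic slot plus observed homotypic pairs) are
standardized into z-scores; a pair is significant when z >= z_threshold
(default 3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from statistics import fmean, stdev
from typing import Mapping

import pandas as pd

from .exceptions import InsufficientPairsError, NoPairsError, PcTraffError
from .pairing import Pair, PairCountTable, canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class PairScoreTable:
    """Per-pair scores over the full scored universe, sorted by z-score."""

    frame: pd.DataFrame  # type_a, type_b, F, p_joint, pmi, pmi_pc, apc,
    #                      pmi_pc_apc, zscore, significant
    type_means: dict[str, float]
    overall_mean: float
    weights: dict[str, float]
    z_threshold: float

    def row(self, type_a: str, type_b: str) -> pd.Series:
        a, b = canonical_pair(type_a, type_b)
        sel = self.frame[(self.frame.type_a == a) & (self.frame.type_b == b)]
        if sel.empty:
            raise KeyError((a, b))
        return sel.iloc[0]

    def zscore(self, type_a: str, type_b: str) -> float:
        return float(self.row(type_a, type_b)["zscore"])

    def rank(self, type_a: str, type_b: str) -> int:
        """1-based rank of a pair in descending z-score order."""
        a, b = canonical_pair(type_a, type_b)
        for pos, (_, r) in enumerate(self.frame.iterrows(), start=1):
            if r.type_a == a and r.type_b == b:
                return pos
        raise KeyError((a, b))

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame.significant]


def pair_probabilities(
    counts: PairCountTable,
) -> tuple[dict[Pair, float], dict[str, float], int]:
    """Joint and slot-marginal probabilities from pooled pair counts."""
    total = counts.total
    if total == 0:
        raise NoPairsError("no pairs")
    p_joint = {pair: F / total for pair, F in counts.pooled.items()}
    occupancy: dict[str, int] = {}
    for (a, b), F in counts.pooled.items():
        if a == b:
            occupancy[a] = occupancy.get(a, 0) + 2 * F
        else:
            occupancy[a] = occupancy.get(a, 0) + F
            occupancy[b] = occupancy.get(b, 0) + F
    p_marginal = {t: c / (2 * total) for t, c in occupancy.items()}
    return p_joint, p_marginal, total


def pair_pmi(
    p_joint: Mapping[Pair, float], p_marginal: Mapping[str, float]
) -> dict[Pair, float]:
    """log2 p(a,b) / (p(a) p(b)) for every observed pair."""
    return {
        (a, b): math.log2(p / (p_marginal[a] * p_marginal[b]))
        for (a, b), p in p_joint.items()
    }


def sequence_weights(counts: PairCountTable) -> dict[str, float]:
    """w_s = N_s / sum N_s; sequences without pairs get weight 0."""
    total = sum(counts.n_s.values())
    if total == 0:
        raise NoPairsError("no pairs in any sequence")
    return {s: n / total for s, n in counts.n_s.items()}


def cumulative_weighted_pmi(
    counts: PairCountTable,
    p_joint: Mapping[Pair, float],
    pmi: Mapping[Pair, float],
    weights: Mapping[str, float],
) -> dict[Pair, float]:
    """PMI_pc(a,b): pooled p * pooled PMI, summed over containing sequences' weights."""
    w_sums: dict[Pair, float] = {}
    for (s, pair), c in counts.per_sequence.items():
        if c > 0:
            w_sums[pair] = w_sums.get(pair, 0.0) + weights[s]
    return {pair: w_sums[pair] * p_joint[pair] * pmi[pair] for pair in p_joint}


def apc_correct(
    pmi_pc: Mapping[Pair, float],
) -> tuple[dict[Pair, float], dict[Pair, float], dict[str, float], float]:
    """Average product correction over the participating-type universe.

    Returns (apc, corrected, type_means, overall_mean) where apc/corrected
    cover every heterotypic slot of the participating types (unobserved
    slots enter with PMI_pc = 0) plus observed homotypic pairs.
    """
    types = sorted({t for pair in pmi_pc for t in pair})
    n = len(types)
    if n < 2:
        raise PcTraffError("fewer than 2 TFBS types participate in pairs")
    het_slots = [canonical_pair(a, b) for a, b in combinations(types, 2)]
    full: dict[Pair, float] = {slot: pmi_pc.get(slot, 0.0) for slot in het_slots}
    for pair, v in pmi_pc.items():
        if pair[0] == pair[1]:
            full[pair] = v

    # the per-type mean sums over all x = 1..n (self term included when the
    # homotypic pair was observed, 0 otherwise) but divides by n - 1
    type_means = {
        a: sum(full.get(canonical_pair(a, x), 0.0) for x in types) / (n - 1)
        for a in types
    }
    overall_mean = sum(full.values()) / len(full)
    if overall_mean == 0.0:
        logger.warning("overall mean PMI_pc is 0; APC defined as 0 (degenerate)")
        apc = {pair: 0.0 for pair in full}
    else:
        apc = {
            (a, b): type_means[a] * type_means[b] / overall_mean
            for (a, b) in full
        }
    corrected = {pair: full[pair] - apc[pair] for pair in full}
    return apc, corrected, type_means, overall_mean


def zscores(
    corrected: Mapping[Pair, float],
    n_observed: int,
    z_threshold: float = 3.0,
) -> tuple[dict[Pair, float], dict[Pair, bool]]:
    """Standardize corrected scores over the scored universe.

    Uses the sample standard deviation; a zero spread yields no significant
    pairs.  Requires at least two observed pairs.
    """
    if n_observed < 2:
        raise InsufficientPairsError("fewer than 2 observed pairs")
    values = list(corrected.values())
    mu = fmean(values)
    sd = stdev(values) if len(values) > 1 else 0.0
    if sd == 0.0:
        logger.warning("corrected scores have zero spread; no significant pairs")
        z = {pair: 0.0 for pair in corrected}
        return z, {pair: False for pair in corrected}
    z = {pair: (v - mu) / sd for pair, v in corrected.items()}
    return z, {pair: z[pair] >= z_threshold for pair in z}


def score_pairs(counts: PairCountTable, z_threshold: float = 3.0) -> PairScoreTable:
    """Run Phases 5-6 on a pair count table."""
    p_joint, p_marginal, _ = pair_probabilities(counts)
    pmi = pair_pmi(p_joint, p_marginal)
    weights = sequence_weights(counts)
    pmi_pc = cumulative_weighted_pmi(counts, p_joint, pmi, weights)
    apc, corrected, type_means, overall_mean = apc_correct(pmi_pc)
    z, sig = zscores(corrected, n_observed=len(counts.pooled),
                     z_threshold=z_threshold)

    rows = []
    for (a, b), corr in corrected.items():
        rows.append(
            {
                "type_a": a,
                "type_b": b,
                "F": counts.pooled.get((a, b), 0),
                "p_joint": p_joint.get((a, b), float("nan")),
                "pmi": pmi.get((a, b), float("nan")),
                "pmi_pc": pmi_pc.get((a, b), 0.0),
                "apc": apc[(a, b)],
                "pmi_pc_apc": corr,
                "zscore": z[(a, b)],
                "significant": sig[(a, b)],
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["type_a", "type_b", "F", "p_joint", "pmi", "pmi_pc", "apc",
                 "pmi_pc_apc", "zscore", "significant"],
    ).sort_values(
        ["zscore", "type_a", "type_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return PairScoreTable(
        frame=frame,
        type_means=type_means,
        overall_mean=overall_mean,
        weights=weights,
        z_threshold=z_threshold,
    )
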