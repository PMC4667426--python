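"""Independent brute-force oracle: straight-from-the-formulas reimplementation
of the PMI quantities using exact rational arithmetic (fractions.Fraction).

Deliberately shares no code with the package; used to cross-check the
implementation on small random instances.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

Pair = tuple[str, str]


def sequence_pmi_oracle(f: list[list[int]]) -> dict[tuple[int, int], float]:
    """PMI(s_i; t_j) = log2( p(s_i,t_j) / (p(s_i) p(t_j)) ) for cells f_ij > 0."""
    m, n = len(f), len(f[0])
    T = sum(sum(row) for row in f)
    row_sums = [sum(row) for row in f]
    col_sums = [sum(f[i][j] for i in range(m)) for j in range(n)]
    out = {}
    for i in range(m):
        for j in range(n):
            if f[i][j] > 0:
                p_joint = Fraction(f[i][j], T)
                p_row = Fraction(row_sums[i], T)
                p_col = Fraction(col_sums[j], T)
                out[(i, j)] = math.log2(p_joint / (p_row * p_col))
    return out


def pair_scores_oracle(
    per_sequence: dict[tuple[str, Pair], int],
) -> dict[str, dict]:
    """All pair-level quantities (joint/marginal probabilities, PMI, sequence
    weights, weighted cumulative PMI, APC, corrected scores, z-scores) from a
    per-sequence pair-count dictionary."""
    pooled: dict[Pair, int] = {}
    n_s: dict[str, int] = {}
    for (s, pair), c in per_sequence.items():
        pooled[pair] = pooled.get(pair, 0) + c
        n_s[s] = n_s.get(s, 0) + c
    T = sum(pooled.values())

    p_joint = {pair: Fraction(F, T) for pair, F in pooled.items()}
    occ: dict[str, int] = {}
    for (a, b), F in pooled.items():
        if a == b:
            occ[a] = occ.get(a, 0) + 2 * F
        else:
            occ[a] = occ.get(a, 0) + F
            occ[b] = occ.get(b, 0) + F
    p_marg = {t: Fraction(c, 2 * T) for t, c in occ.items()}

    pmi = {
        (a, b): math.log2(p / (p_marg[a] * p_marg[b]))
        for (a, b), p in p_joint.items()
    }

    n_total = sum(n_s.values())
    w = {s: Fraction(n, n_total) for s, n in n_s.items()}

    pmi_pc = {}
    for pair in pooled:
        w_sum = sum(
            (w[s] for (s, q), c in per_sequence.items() if q == pair and c > 0),
            start=Fraction(0),
        )
        pmi_pc[pair] = float(w_sum * p_joint[pair]) * pmi[pair]

    types = sorted({t for pair in pooled for t in pair})
    n = len(types)
    key = lambda a, b: (a, b) if a <= b else (b, a)
    full = {key(a, b): pmi_pc.get(key(a, b), 0.0) for a, b in combinations(types, 2)}
    for pair, v in pmi_pc.items():
        if pair[0] == pair[1]:
            full[pair] = v
    means = {
        a: sum(full.get(key(a, x), 0.0) for x in types) / (n - 1) for a in types
    }
    overall = sum(full.values()) / len(full)
    if overall == 0.0:
        apc = {pair: 0.0 for pair in full}
    else:
        apc = {(a, b): means[a] * means[b] / overall for (a, b) in full}
    corrected = {pair: full[pair] - apc[pair] for pair in full}

    vals = list(corrected.values())
    mu = sum(vals) / len(vals)
    if len(vals) > 1:
        var = sum((v - mu) ** 2 for v in vals) / (len(vals) - 1)
        sd = math.sqrt(var)
    else:
        sd = 0.0
    z = {
        pair: ((v - mu) / sd if sd > 0 else 0.0) for pair, v in corrected.items()
    }

    return {
        "pooled": pooled,
        "p_joint": {k: float(v) for k, v in p_joint.items()},
        "p_marginal": {k: float(v) for k, v in p_marg.items()},
        "pmi": pmi,
        "weights": {k: float(v) for k, v in w.items()},
        "pmi_pc": pmi_pc,
        "type_means": means,
        "overall_mean": overall,
        "apc": apc,
        "corrected": corrected,
        "zscore": z,
    }
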