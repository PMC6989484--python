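"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's vectorised code paths: plain
Python loops, direct count enumeration, explicit pair enumeration.
"""

from __future__ import annotations


def pair_auc(pos, neg) -> float:
    """Mann-Whitney probability by explicit enumeration of all pairs."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_orientation(pos, neg) -> int:
    return 1 if pair_auc(pos, neg) >= 0.5 else -1


def brute_fitness(pos, neg, x, orientation=None) -> float:
    """fitness = FN/(FN + (P/N) FP) with FN = #{pos <= x}, FP = #{neg > x}
    in oriented values; 0/0 -> 0.5."""
    if orientation is None:
        orientation = brute_orientation(pos, neg)
    if orientation < 0:
        pos = [-v for v in pos]
        neg = [-v for v in neg]
        x = -x
    fn = sum(1 for v in pos if v <= x)
    fp = sum(1 for v in neg if v > x)
    den = fn + (len(pos) / len(neg)) * fp
    return 0.5 if den == 0 else fn / den


def brute_relevance(pos, neg) -> float:
    """Clamped Youden index of the fitness>0.5 classifier on the training
    values themselves."""
    ori = brute_orientation(pos, neg)
    sens = sum(1 for v in pos if brute_fitness(pos, neg, v, ori) > 0.5) / len(pos)
    spec = sum(1 for v in neg if brute_fitness(pos, neg, v, ori) <= 0.5) / len(neg)
    return max(sens + spec - 1.0, 0.0)
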