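"""Independent brute-force oracles used to freeze expected test values.

Everything here is exact combinatorics on tiny inputs (Fractions, full
enumeration), deliberately sharing no code with the implementation under
test.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by direct summation of the exact pmf."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def hypergeom_by_enumeration(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by enumerating every size-n draw from the universe."""
    favorable = 0
    total = 0
    marked = set(range(K))
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            favorable += 1
    return Fraction(favorable, total)


def fisher_two_sided(table) -> Fraction:
    """Two-sided Fisher p: sum of conditional table probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    total = comb(r1 + r2, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), total)

    observed = prob(a)
    acc = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= observed:
            acc += prob(x)
    return acc


def auc_by_pair_counting(cases, controls) -> Fraction:
    """P(case > control) + P(tie)/2 over all case/control pairs."""
    wins = ties = 0
    for x in cases:
        for y in controls:
            if x > y:
                wins += 2
            elif x == y:
                ties += 1
    return Fraction(2 * wins + 2 * ties, 4 * len(cases) * len(controls))


def bh_step_up(p_values):
    """Benjamini-Hochberg adjusted p-values by the textbook recursion."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted
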