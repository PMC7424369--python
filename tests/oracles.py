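"""Independent reference implementations used only to verify the package.

Everything here is brute force: exact rational arithmetic, exhaustive
enumeration, or naive double loops. None of it shares code with the
implementation under test.
"""

from fractions import Fraction
from math import comb

import numpy as np


def binom_upper_tail_exact(k: int, n: int) -> Fraction:
    """P(X >= k), X ~ Binomial(n, 1/2), as an exact rational term-by-term sum."""
    return 1 - Fraction(sum(comb(n, i) for i in range(k)), 2**n)


def naive_pair_summaries(matrix) -> dict:
    """Double-loop pair direction counts keyed by (gene_a, gene_b), a < b."""
    genes = sorted(matrix.index.astype(str))
    out = {}
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            va = matrix.loc[ga].to_numpy()
            vb = matrix.loc[gb].to_numpy()
            n_gt = int((va > vb).sum())
            n_lt = int((va < vb).sum())
            out[(ga, gb)] = (n_gt, n_lt, len(va) - n_gt - n_lt)
    return out


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration of all tables with the
    observed margins, summing the probabilities of tables no more likely than
    the observed one. Exact rational arithmetic throughout."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return total


def hypergeom_upper_tail_exact(x: int, n_universe: int, k_set: int, q: int) -> Fraction:
    """P(X >= x) for X ~ Hypergeometric(N, K, q), exact combinatorial sum."""
    denom = comb(n_universe, q)
    total = Fraction(0)
    for i in range(x, min(k_set, q) + 1):
        total += Fraction(comb(k_set, i) * comb(n_universe - k_set, q - i), denom)
    return total


def mwu_complete_separation_p(n1: int, n2: int) -> float:
    """Exact two-sided MWU p when one group's values all exceed the other's.

    Only 1 of the C(n1+n2, n1) equally likely label assignments is as extreme
    in each tail, so p = 2 / C(n1+n2, n1)."""
    return 2.0 / comb(n1 + n2, n1)


def template_reversals_naive(values1: np.ndarray, values2: np.ndarray) -> int:
    """Double-loop count of pairs ordered oppositely by two value vectors."""
    count = 0
    g = len(values1)
    for i in range(g):
        for j in range(i + 1, g):
            s1 = np.sign(values1[i] - values1[j])
            s2 = np.sign(values2[i] - values2[j])
            if s1 != s2:
                count += 1
    return count
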