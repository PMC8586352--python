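"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths (and, where possible, the libraries)
they are used to verify.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_greater_exact(both, a_only, b_only, neither) -> float:
    """One-sided (greater) Fisher p by exhaustive hypergeometric enumeration.

    Enumerates every 2x2 table with the observed margins using exact rational
    arithmetic, summing P(table) over tables with at least the observed count
    in the top-left cell.
    """
    row1 = both + a_only
    col1 = both + b_only
    n = both + a_only + b_only + neither
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    denom = comb(n, col1)
    total = Fraction(0)
    for k in range(both, hi + 1):
        total += Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
    # guard: probabilities over the full support must sum to 1
    full = sum(
        Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
        for k in range(lo, hi + 1)
    )
    assert full == 1
    return float(total)


def fisher_two_sided_exact(both, a_only, b_only, neither) -> float:
    """Two-sided Fisher p: sum of table probabilities <= observed table's."""
    row1 = both + a_only
    col1 = both + b_only
    n = both + a_only + b_only + neither
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    denom = comb(n, col1)
    probs = {
        k: Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[both]
    return float(sum(p for p in probs.values() if p <= p_obs))


def bh_stepup(pvals):
    """Hand implementation of Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end  # 1-based rank of this p in ascending order
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)


def pearson_two_pass(x, y) -> float:
    """Textbook two-pass Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))
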