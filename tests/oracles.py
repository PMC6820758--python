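"""Brute-force exact-arithmetic oracles, independent of the implementation.

Every probability here is a Fraction built from factorials, and every
"as or less probable" comparison is decided in exact rational arithmetic,
so these enumerations are free of the floating-point and pruning choices
the library makes.
"""

from fractions import Fraction
from math import comb, factorial


def fisher_2x2_pvalue(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p-value by full enumeration with rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if c1 == 0 or c1 == n or r1 == 0 or r1 == n:
        return Fraction(1)
    denom = comb(n, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def fisher_2x3_pvalue(row1: tuple, row2: tuple) -> Fraction:
    """Two-sided 2x3 conditional exact (Freeman-Halton) p-value by enumeration."""
    u, l = sum(row1), sum(row2)
    cols = tuple(x + y for x, y in zip(row1, row2))
    n = u + l
    if u == 0 or l == 0 or sum(m > 0 for m in cols) < 2:
        return Fraction(1)
    denom = Fraction(factorial(n), factorial(u) * factorial(l))
    for m in cols:
        denom /= factorial(m)

    def prob(a, b):
        cells = (a, b, u - a - b, cols[0] - a, cols[1] - b, cols[2] - (u - a - b))
        num = Fraction(1)
        for cell in cells:
            num /= factorial(cell)
        return num / denom

    probs = []
    obs = None
    for a in range(min(u, cols[0]) + 1):
        for b in range(min(u - a, cols[1]) + 1):
            c = u - a - b
            if c > cols[2] or cols[0] - a > l - (cols[1] - b) + (cols[2] - c):
                pass
            if cols[0] - a < 0 or cols[1] - b < 0 or cols[2] - c < 0:
                continue
            p = prob(a, b)
            probs.append(p)
            if (a, b) == (row1[0], row1[1]):
                obs = p
    assert abs(sum(probs) - 1) == 0, "enumeration must cover the full support"
    return sum(p for p in probs if p <= obs)


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact HWE p-value by full enumeration of heterozygote counts."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return Fraction(1)

    def weight(h):
        return Fraction(
            2**h * factorial(n),
            factorial((n_a - h) // 2) * factorial(h) * factorial((n_b - h) // 2),
        )

    hets = range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    p_obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= p_obs) / total


def all_2x2_tables(max_total: int):
    """Every 2x2 table of nonnegative counts with 0 < total <= max_total."""
    for n in range(1, max_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield a, b, c, n - a - b - c
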