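"""Independent brute-force oracles used only by the test suite."""

from fractions import Fraction
from math import comb


def fet_tail_enumeration(a: int, b: int, c: int, d: int, tail: str) -> float:
    """One-sided Fisher p by exhaustive enumeration of fixed-margin tables.

    Exact rational arithmetic; the concordant tail fixes the margins of the
    (a, b)/(c, d) layout and sums tables with d' >= d, the discordant tail
    does the same on the U<->D-relabelled layout (a, b)/(d, c) with c' >= c.
    Independent of the package implementation (binomial coefficients and a
    full scan over admissible tables, no hypergeometric shortcuts).
    """
    if tail == "discordant":
        return fet_tail_enumeration(a, b, d, c, "concordant")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    total = Fraction(0)
    denom = comb(n, c1)
    for dd in range(0, min(r2, c2) + 1):
        cc = r2 - dd
        bb = c2 - dd
        aa = r1 - bb
        if min(aa, bb, cc) < 0:
            continue
        if dd >= d:
            total += Fraction(comb(r1, aa) * comb(r2, cc), denom)
    return float(total)


def all_tables_up_to(n_max: int):
    """Every non-negative (a, b, c, d) with a+b+c+d <= n_max."""
    for n in range(n_max + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield a, b, c, n - a - b - c
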