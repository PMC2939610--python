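"""Independent exact oracles used by the test suite.

Everything here is computed in rational arithmetic (fractions/math.comb)
or by brute-force enumeration, deliberately sharing no code path with the
package implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction


def beta_rational(a: int, b: int) -> Fraction:
    """B(a, b) for positive integers via the factorial identity
    B(x+1, y+1) = x! y! / (x+y+1)!."""
    x, y = a - 1, b - 1
    return Fraction(math.factorial(x) * math.factorial(y), math.factorial(x + y + 1))


def bfln_rational(n0a: int, n1a: int, n2a: int, n0u: int, n1u: int, n2u: int) -> float:
    """Exact-rational Bayes factor of the 2x3 genotype table, returned as
    its natural log (float division of exact integer log terms)."""
    num = (
        beta_rational(n0a + 1, n0u + 1)
        * beta_rational(n1a + 1, n1u + 1)
        * beta_rational(n2a + 1, n2u + 1)
    )
    den = beta_rational(n0a + n1a + n2a + 1, n0u + n1u + n2u + 1)
    bf = num / den
    return math.log(bf.numerator) - math.log(bf.denominator)


def fisher_two_sided_rational(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] by full enumeration of
    the hypergeometric support in exact rational arithmetic."""
    r1, r2, m = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or m == 0 or m == n:
        return 1.0
    total = math.comb(n, m)
    lo, hi = max(0, m - r2), min(r1, m)
    probs = {
        x: Fraction(math.comb(r1, x) * math.comb(r2, m - x), total)
        for x in range(lo, hi + 1)
    }
    observed = probs[a]
    return float(sum(p for p in probs.values() if p <= observed))


def hypergeom_tail_rational(k: int, n_universe: int, n_disease: int, n_category: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact enumeration."""
    total = math.comb(n_universe, n_category)
    hi = min(n_disease, n_category)
    s = sum(
        Fraction(
            math.comb(n_disease, i) * math.comb(n_universe - n_disease, n_category - i),
            total,
        )
        for i in range(max(k, 0), hi + 1)
    )
    return float(s)


def nearest_gene_linear(
    pos: int,
    chrom: str,
    genes: list[tuple[str, str, int, int]],
    max_distance: int,
) -> str | None:
    """Brute-force nearest-interval scan over (gene_id, chrom, start, end)."""
    best = None
    for gid, gchrom, start, end in genes:
        if gchrom != chrom:
            continue
        d = max(0, start - pos, pos - end)
        key = (d, gid)
        if best is None or key < best:
            best = key
    if best is None or best[0] > max_distance:
        return None
    return best[1]
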