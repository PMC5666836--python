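"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
exact rational arithmetic for binomial tails, per-residue bitmaps for
region merging, full hypergeometric enumeration for Fisher's test, and
direct double-loop substring enumeration for CBR calls.
"""

from __future__ import annotations

import math
from decimal import Decimal, getcontext
from fractions import Fraction

getcontext().prec = 50


def log10_tail_exact(L: int, k: int, p: float) -> float:
    """Exact log10 binomial upper tail via rational arithmetic.

    Treats the float ``p`` as its exact binary rational value, sums the tail
    exactly as a Fraction, and takes log10 at 50-digit precision.
    """
    P = Fraction(p)
    q = 1 - P
    total = sum(Fraction(math.comb(L, j)) * P**j * q ** (L - j) for j in range(k, L + 1))
    if total == 0:
        return float("-inf")
    lg = (Decimal(total.numerator).ln() - Decimal(total.denominator).ln()) / Decimal(10).ln()
    return float(lg)


def log10_tail_comb(L: int, k: int, p: float) -> float:
    """Binomial tail via exact combinatorial coefficients + float log-sum-exp.

    Independent of the library's gammaln-based path; used where the exact
    rational oracle would be too slow.
    """
    terms = [
        math.log(math.comb(L, j)) + j * math.log(p) + (L - j) * math.log1p(-p)
        for j in range(k, L + 1)
    ]
    peak = max(terms)
    return (peak + math.log(sum(math.exp(t - peak) for t in terms))) / math.log(10)


def ar_regions_bitmap(
    sequence: str, scores: dict[str, list[float]], w: int, threshold: float,
    min_len: int,
) -> list[tuple[int, int]]:
    """AR calls by marking every residue covered by a positive window.

    ``scores`` maps residue -> per-position score list. Runs of marked
    residues are extracted and length-filtered. Valid because merged regions
    are exactly the union of positive windows.
    """
    n = len(sequence)
    covered = [False] * n
    for start in range(0, n - w + 1):
        s = sum(scores[sequence[start + j]][j] for j in range(w))
        if s >= threshold:
            for j in range(start, start + w):
                covered[j] = True
    regions = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            if j - i >= min_len:
                regions.append((i, j))
            i = j
        else:
            i += 1
    return regions


def cbr_brute_force(
    sequence: str, members: set[str], p: float, threshold: float
) -> list[tuple[int, int, float]]:
    """CBR calls by enumerating every anchored substring directly.

    Double loop over all (start, end) index pairs whose end residues are
    class members; tails via :func:`log10_tail_comb`; greedy
    lowest-probability / longest / leftmost selection of disjoint regions.
    Returns (start, end, log10_tail) sorted by start.
    """
    n = len(sequence)
    log10_thr = math.log10(threshold)
    candidates = []
    for start in range(n):
        if sequence[start] not in members:
            continue
        k = 0
        for end in range(start + 1, n + 1):
            if sequence[end - 1] not in members:
                continue
            k += 1
            L = end - start
            lg = log10_tail_comb(L, k, p)
            if lg < log10_thr:
                candidates.append((lg, -(L), start, end))
    candidates.sort()
    chosen: list[tuple[int, int, float]] = []
    for lg, negL, s, e in candidates:
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, lg))
    return sorted(chosen)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p as an exact Fraction, by full table enumeration.

    With margins fixed, every table is indexed by its top-left cell x; the
    p-value sums P(x') over all x' whose point probability does not exceed
    the observed table's (with an exact-rational comparison, no float
    rounding).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def point(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = point(a)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs)


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n), by direct summation."""
    denom = math.comb(N, n)
    hi = min(K, n)
    return sum(
        Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
        for j in range(k, hi + 1)
    )


def bh_step_up(pvals: list[float]) -> list[float]:
    """Textbook BH: adj_i = min_{j: p_j >= p_i ranked} (m * p_(j) / j), capped at 1."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adjusted[i] = running
    return adjusted
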