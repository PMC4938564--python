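"""Independent brute-force oracles used to check the package's statistics.

These deliberately share no code with the implementation: exact integer
enumeration via ``math.comb`` throughout.
"""

from __future__ import annotations

from math import comb


def hwe_enum_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact HWE p-value by full enumeration with integer arithmetic.

    Conditions on the minor-allele count m and sample size n; enumerates
    every admissible heterozygote count h, counting genotype configurations
    as n!/(a! b! h!) * 2^h, and sums the probabilities of all h whose
    configuration count does not exceed the observed one (exact integer
    comparison, so ties are handled without tolerance).
    """
    n = n_hom_major + n_het + n_hom_minor
    m = 2 * n_hom_minor + n_het
    if m > n:
        m = 2 * n - m
    ways: dict[int, int] = {}
    for h in range(m % 2, m + 1, 2):
        a = (m - h) // 2
        b = n - a - h
        if b < 0:
            continue
        ways[h] = comb(n, h) * comb(n - h, a) * (1 << h)
    total = sum(ways.values())
    w_obs = ways[n_het]
    return sum(w for w in ways.values() if w <= w_obs) / total


def hwe_enum_pvalues_all(n: int, m: int) -> dict[int, float]:
    """p-value for every admissible heterozygote count at (n samples,
    m minor alleles); same enumeration as :func:`hwe_enum_pvalue`."""
    ways: dict[int, int] = {}
    for h in range(m % 2, m + 1, 2):
        a = (m - h) // 2
        b = n - a - h
        if b < 0:
            continue
        ways[h] = comb(n, h) * comb(n - h, a) * (1 << h)
    total = sum(ways.values())
    return {
        h: sum(w2 for w2 in ways.values() if w2 <= w) / total
        for h, w in ways.items()
    }


def hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k), X ~ Hypergeom(N, K, n), by exact integer enumeration."""
    total = comb(N, n)
    num = sum(comb(K, a) * comb(N - K, n - a) for a in range(k, min(K, n) + 1))
    return num / total


def hypergeom_sf_exact_all(N: int, K: int, n: int) -> list[float]:
    """P(X >= k) for k = 0..min(K, n), exact integer suffix sums."""
    kmax = min(K, n)
    terms = [comb(K, a) * comb(N - K, n - a) for a in range(kmax + 1)]
    total = comb(N, n)
    out = []
    suffix = sum(terms)
    for a in range(kmax + 1):
        out.append(suffix / total)
        suffix -= terms[a]
    return out


def weighted_score_moments_rowwise(rows: list[tuple[float, float]]):
    """Spreadsheet-style row-by-row accumulation of weighted-score moments
    under HWE; ``rows`` holds (odds_ratio, freq) pairs."""
    from math import log

    mean = 0.0
    var = 0.0
    for odds_ratio, p in rows:
        beta = log(odds_ratio)
        mean += beta * 2.0 * p
        var += beta * beta * 2.0 * p * (1.0 - p)
    return mean, var
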