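"""Independent brute-force oracles for the exact tests.

These enumerate the full outcome space directly from the probability mass
function and never call the implementations they check.
"""

from math import comb


def binom_pmf(k: int, n: int, p: float) -> float:
    return comb(n, k) * p**k * (1.0 - p) ** (n - k)


def binomial_two_sided_oracle(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-sided binomial p by full enumeration."""
    observed = binom_pmf(k, n, p0)
    # relative tolerance for pmf ties computed in floating point
    cutoff = observed * (1.0 + 1e-7)
    return min(1.0, sum(binom_pmf(i, n, p0) for i in range(n + 1) if binom_pmf(i, n, p0) <= cutoff))


def hypergeom_weight(x: int, r1: int, r2: int, c1: int) -> int:
    """Unnormalized hypergeometric weight for table [[x, r1-x], [c1-x, ...]]."""
    return comb(r1, x) * comb(r2, c1 - x)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Probability-ordering two-sided Fisher p by hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {x: hypergeom_weight(x, r1, r2, c1) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    observed = weights[a] / total
    cutoff = observed * (1.0 + 1e-7)
    return min(
        1.0, sum(w / total for w in weights.values() if w / total <= cutoff)
    )


def bh_oracle(pvals):
    """Step-up BH by the literal formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * m / rank)
        q[i] = running_min
    return q
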