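"""Exact statistical primitives shared by all analysis stages.

Three primitives underlie every significance call in the pipeline: the
two-sided binomial exact test (allelic-bias testing), Fisher's exact test
on 2x2 tables (count comparisons between genotypes), and Benjamini-Hochberg
FDR adjustment.  Both exact tests use the minimum-likelihood two-sided
convention: the p-value sums the probabilities of all outcomes no more
likely than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "binomial_two_sided",
    "fisher_exact_2x2",
    "bh_adjust",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.05


@dataclass
class TestResult:
    """Outcome of a single exact test.

    ``statistic`` is an effect measure on the log2 scale; ``q_value`` is
    filled in after BH adjustment across the relevant family of tests.
    """

    statistic: float
    p_value: float
    q_value: float = field(default=float("nan"))
    significant: bool = False

    def finalize(self, q_value: float, alpha: float = DEFAULT_ALPHA) -> "TestResult":
        self.q_value = float(q_value)
        self.significant = bool(q_value < alpha)
        return self


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided binomial exact p-value by the minimum-likelihood method.

    Sums P(X = i) over every outcome i whose point probability does not
    exceed that of the observed count ``k``, with X ~ Binomial(n, p0).

    Parameters
    ----------
    k : observed success count, 0 <= k <= n.
    n : number of trials, n >= 1.
    p0 : null success probability, 0 < p0 < 1.
    """
    k = int(k)
    n = int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n]; got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    return float(_st.binomtest(k, n, p0, alternative="two-sided").pvalue)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    Two-sidedness by hypergeometric probability-mass ordering (the sum over
    all tables with the observed margins whose probability is <= that of
    the observed table), not by doubling a one-sided tail.
    """
    cells = [int(x) for x in (a, b, c, d)]
    if any(x < 0 for x in cells):
        raise ValueError(f"cell counts must be non-negative, got {cells}")
    if sum(cells) == 0:
        raise ValueError("at least one margin must be positive")
    table = [[cells[0], cells[1]], [cells[2], cells[3]]]
    return float(_st.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns q-values: q_(i) = min_{j >= rank(i)} ( p_(j) * m / j ), clipped
    to 1.  Order-preserving on ranks; every q >= its p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
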