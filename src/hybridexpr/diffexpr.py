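"""Pairwise differential expression between genotypes via exact count tests.

Replicates are pooled per group, library sizes equalized by scaling the
larger group's pooled count down (round half-to-even), and each gene is
tested with Fisher's exact test on the 2x2 table
``[[count_a, rest_of_library_a], [count_b, rest_of_library_b]]``.
Absolute DEG counts are therefore not comparable with shrinkage-based
negative-binomial callers; directions and summary percentages are.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from hybridexpr.stats_core import (
    DEFAULT_ALPHA,
    TestResult,
    bh_adjust,
    fisher_exact_2x2,
)

__all__ = [
    "DEResult",
    "equalize_counts",
    "test_differential",
    "de_table",
    "call_degs",
    "summarize_degs",
    "overlap_sets",
    "replicate_concordance",
]


@dataclass
class DEResult:
    gene_id: str
    group_a: str
    group_b: str
    log2_fold_change: float
    test: TestResult
    direction: str = "ns"  # up / down / ns
    untestable: bool = False


def equalize_counts(
    count_a: int, lib_a: int, count_b: int, lib_b: int
) -> tuple[int, int, int]:
    """Scale the larger-library group's count down to the smaller library.

    Returns integer counts (na, nb) on the common scale plus the common
    library size.  Rounding is half-to-even so exact tests see integers.
    """
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    if lib_a == lib_b:
        return int(count_a), int(count_b), int(lib_a)
    if lib_a > lib_b:
        na = int(np.round(count_a * lib_b / lib_a))
        return na, int(count_b), int(lib_b)
    nb = int(np.round(count_b * lib_a / lib_b))
    return int(count_a), nb, int(lib_a)


def test_differential(
    counts_a: Iterable[int],
    counts_b: Iterable[int],
    libsize_a: int,
    libsize_b: int,
    gene_id: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> DEResult:
    """Exact DE test for one gene between two replicate groups.

    Pools replicates, equalizes library sizes, and runs Fisher's exact
    test of the gene's count against the rest of the library.  The log2
    fold change uses pseudocount 1 on the equalized counts.
    """
    pooled_a = int(np.sum(np.asarray(list(counts_a), dtype=np.int64)))
    pooled_b = int(np.sum(np.asarray(list(counts_b), dtype=np.int64)))
    na, nb, lib = equalize_counts(pooled_a, libsize_a, pooled_b, libsize_b)
    lfc = float(np.log2((na + 1) / (nb + 1)))
    if pooled_a == 0 and pooled_b == 0:
        return DEResult(
            gene_id, group_a, group_b, 0.0, TestResult(0.0, 1.0), "ns", untestable=True
        )
    p = fisher_exact_2x2(na, lib - na, nb, lib - nb)
    return DEResult(gene_id, group_a, group_b, lfc, TestResult(lfc, p))


def de_table(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    group_col: str = "genotype",
) -> pd.DataFrame:
    """Vectorized per-gene DE table between two design groups.

    Returns a DataFrame indexed by gene with columns pooled_a, pooled_b,
    log2_fold_change, p_value, untestable.
    """
    samples_a = design.index[design[group_col] == group_a]
    samples_b = design.index[design[group_col] == group_b]
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError(f"no samples for groups {group_a!r} / {group_b!r}")
    lib_a = int(counts[samples_a].to_numpy().sum())
    lib_b = int(counts[samples_b].to_numpy().sum())
    pooled_a = counts[samples_a].sum(axis=1).to_numpy(np.int64)
    pooled_b = counts[samples_b].sum(axis=1).to_numpy(np.int64)

    na = np.copy(pooled_a)
    nb = np.copy(pooled_b)
    if lib_a > lib_b:
        na = np.round(pooled_a * (lib_b / lib_a)).astype(np.int64)
        lib = lib_b
    elif lib_b > lib_a:
        nb = np.round(pooled_b * (lib_a / lib_b)).astype(np.int64)
        lib = lib_a
    else:
        lib = lib_a

    untestable = (pooled_a == 0) & (pooled_b == 0)
    pvals = np.ones(len(counts))
    for i in range(len(counts)):
        if not untestable[i]:
            pvals[i] = fisher_exact_2x2(
                na[i], lib - na[i], nb[i], lib - nb[i]
            )
    lfc = np.log2((na + 1) / (nb + 1))
    lfc[untestable] = 0.0
    return pd.DataFrame(
        {
            "pooled_a": pooled_a,
            "pooled_b": pooled_b,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "untestable": untestable,
        },
        index=counts.index,
    )


def call_degs(
    de: pd.DataFrame,
    expressed: pd.Series | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Apply the expression filter and BH adjustment, assign directions.

    Genes failing the RPKM filter (``expressed`` false) are excluded
    before adjustment.  Returns the filtered table with q_value and
    direction (up: a > b) columns.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    out = de if expressed is None else de.loc[expressed.reindex(de.index, fill_value=False)]
    out = out.copy()
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    sig = (out["q_value"] < alpha) & ~out["untestable"]
    direction = np.where(
        sig & (out["log2_fold_change"] > 0),
        "up",
        np.where(sig & (out["log2_fold_change"] < 0), "down", "ns"),
    )
    out["direction"] = direction
    return out


def summarize_degs(called: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Up/Down/Total DEG counts and percentages per comparison.

    Percentages are relative to the number of analyzed (filter-passing)
    genes in each comparison.
    """
    rows = []
    for name, df in called.items():
        n = len(df)
        up = int((df["direction"] == "up").sum())
        down = int((df["direction"] == "down").sum())
        total = up + down
        rows.append(
            {
                "comparison": name,
                "analyzed": n,
                "up": up,
                "up_pct": 100.0 * up / n if n else 0.0,
                "down": down,
                "down_pct": 100.0 * down / n if n else 0.0,
                "total": total,
                "total_pct": 100.0 * total / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("comparison")


def overlap_sets(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Venn-region cardinalities for up to three gene sets.

    Returns a dict keyed by the sorted tuple of set names forming each
    exclusive region (genes in exactly those sets) -> region size.
    """
    names = sorted(sets)
    if not 1 <= len(names) <= 3:
        raise ValueError("overlap_sets supports 1-3 sets; report pairwise instead")
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                set(), *(sets[n] for n in names if n not in combo)
            )
            regions[combo] = len(inside - outside)
    return regions


def replicate_concordance(
    rpkm: pd.DataFrame, design: pd.DataFrame, group_col: str = "genotype"
) -> pd.Series:
    """QC: Pearson r of log2(RPKM+1) between replicate pairs per group."""
    out = {}
    for group, sub in design.groupby(group_col):
        samples = list(sub.index)
        for s1, s2 in combinations(samples, 2):
            x = np.log2(rpkm[s1] + 1)
            y = np.log2(rpkm[s2] + 1)
            out[f"{group}:{s1}~{s2}"] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="pearson_r")
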