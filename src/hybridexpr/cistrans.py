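"""Decomposition of parental expression divergence into cis and trans parts.

Per gene, three statistics are tested: A, the log2 parental divergence at
the gene's SNP sites (binomial exact test on library-equalized parental
depths); B, the log2 hybrid allelic divergence (binomial exact test on
the hybrid allele counts, the cis component); and A - B, the trans
component (Fisher's exact test comparing the parental and hybrid allele
tables).  The significance pattern assigns one of five categories —
cis_only, trans_only, cis_trans, conserved, ambiguous — and cis_trans
genes are split into enhancing vs compensating interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hybridexpr.stats_core import (
    DEFAULT_ALPHA,
    bh_adjust,
    binomial_two_sided,
    fisher_exact_2x2,
)

__all__ = [
    "CATEGORIES",
    "RegulatoryCall",
    "test_parental_divergence",
    "test_cis",
    "test_trans",
    "classify_regulation",
    "percent_cis",
    "analyze_regulation",
    "percent_cis_binned",
    "crosstab_regulation_inheritance",
    "summarize_categories",
]

CATEGORIES = ("cis_only", "trans_only", "cis_trans", "conserved", "ambiguous")

MIN_PARENT_DEPTH = 10
ABS_A_BINS = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, np.inf)
ABS_A_LABELS = ("0-1", "1-2", "2-3", "3-4", "4-5", ">5")


@dataclass
class RegulatoryCall:
    gene_id: str
    A: float
    B: float
    trans_component: float
    p_A: float
    p_B: float
    p_AB: float
    category: str
    interaction: str  # enhancing / compensating / none
    percent_cis: float


def test_parental_divergence(p1: int, p2: int) -> tuple[float, float]:
    """(A, p) for the parental divergence at SNP sites.

    A = log2((p1+1)/(p2+1)); p from the two-sided binomial test of p1
    successes in p1+p2 trials at 0.5.  Both counts zero -> untestable
    (p = NaN).
    """
    a = float(np.log2((p1 + 1) / (p2 + 1)))
    if p1 + p2 == 0:
        return a, float("nan")
    return a, binomial_two_sided(p1, p1 + p2, 0.5)


def test_cis(maternal_hyb: int, paternal_hyb: int) -> tuple[float, float]:
    """(B, p) for the hybrid allelic divergence (the cis component)."""
    b = float(np.log2((maternal_hyb + 1) / (paternal_hyb + 1)))
    if maternal_hyb + paternal_hyb == 0:
        return b, float("nan")
    return b, binomial_two_sided(maternal_hyb, maternal_hyb + paternal_hyb, 0.5)


def test_trans(
    p1: int, p2: int, maternal_hyb: int, paternal_hyb: int
) -> float:
    """p-value for the trans component A - B.

    Fisher's exact test on [[p1, p2], [maternal_hyb, paternal_hyb]]: does
    the parental ratio differ from the hybrid allelic ratio?  Untestable
    (NaN) when either table row is empty.
    """
    if p1 + p2 == 0 or maternal_hyb + paternal_hyb == 0:
        return float("nan")
    return fisher_exact_2x2(p1, p2, maternal_hyb, paternal_hyb)


def classify_regulation(
    sig_A: bool,
    sig_B: bool,
    sig_AB: bool,
    A: float,
    B: float,
    convention: str = "paper",
) -> tuple[str, str]:
    """Category and interaction from the three significance flags.

    Truth table: cis_only = sig A, sig B, no sig A-B; trans_only = sig A,
    no sig B, sig A-B; cis_trans = all three significant; conserved =
    none significant; ambiguous = every other pattern.

    For cis_trans genes the interaction is enhancing when the parental
    and hybrid allelic ratios share a direction, compensating otherwise.
    ``convention='paper'`` compares sign(A) with sign(B);
    ``convention='cis-vs-trans'`` compares sign(B) with sign(A - B).
    """
    if sig_A and sig_B and not sig_AB:
        return "cis_only", "none"
    if sig_A and not sig_B and sig_AB:
        return "trans_only", "none"
    if sig_A and sig_B and sig_AB:
        if convention == "paper":
            same = np.sign(A) == np.sign(B)
        elif convention == "cis-vs-trans":
            same = np.sign(B) == np.sign(A - B)
        else:
            raise ValueError(f"unknown convention {convention!r}")
        return "cis_trans", ("enhancing" if same else "compensating")
    if not sig_A and not sig_B and not sig_AB:
        return "conserved", "none"
    return "ambiguous", "none"


def percent_cis(A: float, B: float) -> float:
    """|B| / (|B| + |A - B|) * 100; NaN when both magnitudes are zero."""
    denom = abs(B) + abs(A - B)
    if denom == 0:
        return float("nan")
    return 100.0 * abs(B) / denom


def analyze_regulation(
    gene_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_parent_depth: int = MIN_PARENT_DEPTH,
    convention: str = "paper",
    equalize_parents: bool = True,
) -> pd.DataFrame:
    """Full cis/trans decomposition for a per-gene allele-count table.

    ``gene_table`` is indexed by gene with columns maternal_total,
    paternal_total (hybrid allele sums) and maternal_parent_depth,
    paternal_parent_depth (summed parental site depths).  Parental depths
    are library-equalized (larger parent scaled down, round half-to-even)
    before testing; genes with combined parental depth below
    ``min_parent_depth`` or zero hybrid coverage are excluded.

    The three p-value families are BH-adjusted separately across genes.
    """
    df = gene_table.copy()
    p1 = df["maternal_parent_depth"].to_numpy(np.int64)
    p2 = df["paternal_parent_depth"].to_numpy(np.int64)
    if equalize_parents:
        t1, t2 = int(p1.sum()), int(p2.sum())
        if t1 > t2 and t2 > 0:
            p1 = np.round(p1 * (t2 / t1)).astype(np.int64)
        elif t2 > t1 and t1 > 0:
            p2 = np.round(p2 * (t1 / t2)).astype(np.int64)
    m = df["maternal_total"].to_numpy(np.int64)
    p = df["paternal_total"].to_numpy(np.int64)

    keep = (p1 + p2 >= min_parent_depth) & (m + p > 0)
    df = df.loc[keep]
    p1, p2, m, p = p1[keep], p2[keep], m[keep], p[keep]

    n = len(df)
    A = np.log2((p1 + 1) / (p2 + 1))
    B = np.log2((m + 1) / (p + 1))
    pA = np.empty(n)
    pB = np.empty(n)
    pAB = np.empty(n)
    for i in range(n):
        pA[i] = binomial_two_sided(p1[i], p1[i] + p2[i], 0.5)
        pB[i] = binomial_two_sided(m[i], m[i] + p[i], 0.5)
        pAB[i] = fisher_exact_2x2(p1[i], p2[i], m[i], p[i])

    out = pd.DataFrame(
        {
            "parent1_eq": p1,
            "parent2_eq": p2,
            "maternal_total": m,
            "paternal_total": p,
            "A": A,
            "B": B,
            "trans_component": A - B,
            "p_A": pA,
            "p_B": pB,
            "p_AB": pAB,
            "q_A": bh_adjust(pA),
            "q_B": bh_adjust(pB),
            "q_AB": bh_adjust(pAB),
        },
        index=df.index,
    )
    cats = []
    inter = []
    for row in out.itertuples():
        c, i = classify_regulation(
            row.q_A < alpha,
            row.q_B < alpha,
            row.q_AB < alpha,
            row.A,
            row.B,
            convention=convention,
        )
        cats.append(c)
        inter.append(i)
    out["category"] = cats
    out["interaction"] = inter
    out["percent_cis"] = [percent_cis(a, b) for a, b in zip(out["A"], out["B"])]
    return out


def percent_cis_binned(calls: pd.DataFrame) -> pd.DataFrame:
    """Summary statistics of percent_cis per |A| magnitude bin."""
    df = calls.dropna(subset=["percent_cis"]).copy()
    df["abs_A_bin"] = pd.cut(
        df["A"].abs(), bins=list(ABS_A_BINS), labels=list(ABS_A_LABELS),
        right=False, include_lowest=True,
    )
    return (
        df.groupby("abs_A_bin", observed=False)["percent_cis"]
        .agg(["count", "mean", "median", "std"])
    )


def crosstab_regulation_inheritance(
    reg_calls: pd.DataFrame, inh_calls: pd.DataFrame
) -> pd.DataFrame:
    """Contingency of regulatory category x inheritance mode on shared genes."""
    shared = reg_calls.index.intersection(inh_calls.index)
    if len(shared) == 0:
        import warnings

        warnings.warn("no shared genes between call sets", stacklevel=2)
        return pd.DataFrame()
    return pd.crosstab(
        reg_calls.loc[shared, "category"].rename("category"),
        inh_calls.loc[shared, "mode"].rename("mode"),
    )


def summarize_categories(calls: pd.DataFrame) -> pd.DataFrame:
    """Category counts/percentages with the enhancing/compensating split."""
    n = len(calls)
    rows = []
    for cat in CATEGORIES:
        cnt = int((calls["category"] == cat).sum())
        rows.append((cat, cnt, 100.0 * cnt / n if n else float("nan")))
    ct = calls[calls["category"] == "cis_trans"]
    for inter in ("enhancing", "compensating"):
        cnt = int((ct["interaction"] == inter).sum())
        rows.append(
            (
                f"cis_trans_{inter}",
                cnt,
                100.0 * cnt / len(ct) if len(ct) else float("nan"),
            )
        )
    return pd.DataFrame(rows, columns=["category", "count", "percent"]).set_index(
        "category"
    )
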