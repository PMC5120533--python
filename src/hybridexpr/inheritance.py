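"""Classification of hybrid expression inheritance against the mid-parent value.

Each analyzed gene is assigned one mode: additive (hybrid indistinguishable
from the mid-parent value) or one of the non-additive classes —
over-dominance, high-/low-parent dominance, under-dominance, conserved
(significantly different from mid-parent and both parents yet within the
parental range) — with an unclassifiable bucket for ambiguous patterns.
All four underlying comparisons (hybrid vs MPV, hybrid vs each parent,
parent vs parent) use Fisher's exact test of the gene's pooled count
against the rest of the library, FDR-adjusted separately per comparison
family across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hybridexpr.stats_core import DEFAULT_ALPHA, bh_adjust, fisher_exact_2x2

__all__ = [
    "MODES",
    "InheritanceCall",
    "midparent_counts",
    "inheritance_tests",
    "classify_inheritance",
    "classify_single",
    "summarize_modes",
    "compare_stage_modes",
]

MODES = (
    "additive",
    "over_dominance",
    "high_parent_dominance",
    "low_parent_dominance",
    "under_dominance",
    "conserved",
    "unclassifiable",
)

NON_ADDITIVE = MODES[1:6]


@dataclass
class InheritanceCall:
    gene_id: str
    mode: str
    dominant_parent: str  # maternal / paternal / none
    p_mpv: float
    p_maternal: float
    p_paternal: float
    p_parents: float


def midparent_counts(p1: float, p2: float) -> int:
    """Mid-parent pseudo-sample count: round half-to-even mean of the
    library-equalized parental pooled counts."""
    return int(np.round((p1 + p2) / 2.0))


def _equalize_to_common(pooled: np.ndarray, libs: np.ndarray) -> tuple[np.ndarray, int]:
    """Scale each genotype's pooled counts to the smallest library."""
    common = int(libs.min())
    out = np.empty_like(pooled)
    for j, lib in enumerate(libs):
        if lib == common:
            out[:, j] = pooled[:, j]
        else:
            out[:, j] = np.round(pooled[:, j] * (common / lib)).astype(np.int64)
    return out, common


def inheritance_tests(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    maternal: str = "P1",
    paternal: str = "P2",
    hybrid: str = "F1",
    group_col: str = "genotype",
) -> pd.DataFrame:
    """Per-gene counts and raw p-values for the four comparison families.

    Replicates are pooled per genotype, all three genotypes are equalized
    to the smallest library, and the MPV pseudo-sample is materialized as
    the rounded mean of the equalized parental counts.  Returns a
    DataFrame with equalized counts (hyb, p1, p2, mpv), the common
    library size, and raw p-values p_mpv, p_p1, p_p2, p_pp.
    """
    groups = {}
    libs = []
    for g in (maternal, paternal, hybrid):
        samples = design.index[design[group_col] == g]
        if len(samples) == 0:
            raise ValueError(f"no samples for genotype {g!r} in design")
        groups[g] = counts[samples].sum(axis=1).to_numpy(np.int64)
        libs.append(int(counts[samples].to_numpy().sum()))
    pooled = np.column_stack([groups[maternal], groups[paternal], groups[hybrid]])
    eq, lib = _equalize_to_common(pooled, np.asarray(libs))
    p1, p2, hyb = eq[:, 0], eq[:, 1], eq[:, 2]
    mpv = np.round((p1 + p2) / 2.0).astype(np.int64)

    n = len(counts)
    out = pd.DataFrame(
        {"hyb": hyb, "p1": p1, "p2": p2, "mpv": mpv},
        index=counts.index,
    )
    for col, (x, y) in {
        "p_mpv": (hyb, mpv),
        "p_p1": (hyb, p1),
        "p_p2": (hyb, p2),
        "p_pp": (p1, p2),
    }.items():
        pv = np.ones(n)
        for i in range(n):
            if x[i] or y[i]:
                pv[i] = fisher_exact_2x2(x[i], lib - x[i], y[i], lib - y[i])
        out[col] = pv
    out.attrs["library_size"] = lib
    return out


def _decide(
    hyb: int,
    p1: int,
    p2: int,
    sig_mpv: bool,
    sig_p1: bool,
    sig_p2: bool,
) -> tuple[str, str]:
    """Decision sequence for one gene.  Returns (mode, dominant_parent)."""
    if hyb == 0 and p1 == 0 and p2 == 0:
        return "unclassifiable", "none"
    if not sig_mpv:
        return "additive", "none"
    if sig_p1 and sig_p2:
        if hyb > p1 and hyb > p2:
            return "over_dominance", "none"
        if hyb < p1 and hyb < p2:
            return "under_dominance", "none"
        return "conserved", "none"
    if sig_p1 != sig_p2:
        # indistinguishable from exactly one parent -> dominance
        matched_is_maternal = not sig_p1
        matched, other = (p1, p2) if matched_is_maternal else (p2, p1)
        if matched == other:
            return "unclassifiable", "none"
        parent = "maternal" if matched_is_maternal else "paternal"
        mode = "high_parent_dominance" if matched > other else "low_parent_dominance"
        return mode, parent
    # indistinguishable from both parents while != MPV
    return "unclassifiable", "none"


def classify_inheritance(
    tests: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Assign inheritance modes from the per-gene test table.

    Each of the four p-value families is BH-adjusted separately across
    genes before applying the decision sequence.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    out = tests.copy()
    for col in ("p_mpv", "p_p1", "p_p2", "p_pp"):
        out["q" + col[1:]] = bh_adjust(out[col].to_numpy())
    modes = []
    parents = []
    for row in out.itertuples():
        mode, parent = _decide(
            row.hyb,
            row.p1,
            row.p2,
            row.q_mpv < alpha,
            row.q_p1 < alpha,
            row.q_p2 < alpha,
        )
        modes.append(mode)
        parents.append(parent)
    out["mode"] = modes
    out["dominant_parent"] = parents
    return out


def classify_single(
    hybrid: int,
    p1: int,
    p2: int,
    library_size: int,
    alpha: float = DEFAULT_ALPHA,
    gene_id: str = "",
) -> InheritanceCall:
    """Classify one gene in isolation (q-values equal raw p-values)."""
    lib = int(library_size)
    mpv = midparent_counts(p1, p2)

    def _p(x: int, y: int) -> float:
        if x == 0 and y == 0:
            return 1.0
        return fisher_exact_2x2(x, lib - x, y, lib - y)

    p_mpv = _p(hybrid, mpv)
    p_m = _p(hybrid, p1)
    p_f = _p(hybrid, p2)
    p_pp = _p(p1, p2)
    mode, parent = _decide(
        hybrid, p1, p2, p_mpv < alpha, p_m < alpha, p_f < alpha
    )
    return InheritanceCall(gene_id, mode, parent, p_mpv, p_m, p_f, p_pp)


def summarize_modes(calls: pd.DataFrame) -> pd.DataFrame:
    """Mode counts and percentages, dominance classes split by parent.

    Percentages for additive/non-additive are over classified genes
    (unclassifiable excluded); class shares are over the non-additive
    total, mirroring the usual presentation.
    """
    if len(calls) == 0:
        return pd.DataFrame(columns=["count", "percent"])
    mode = calls["mode"]
    parent = calls.get(
        "dominant_parent", pd.Series("none", index=calls.index)
    )
    classified = int((mode != "unclassifiable").sum())
    additive = int((mode == "additive").sum())
    non_additive = classified - additive
    rows: list[tuple[str, int, float]] = [
        ("additive", additive, _pct(additive, classified)),
        ("non_additive", non_additive, _pct(non_additive, classified)),
    ]
    for label, m in [
        ("over_dominance", "over_dominance"),
        ("high_parent_dominance_maternal", None),
        ("high_parent_dominance_paternal", None),
        ("low_parent_dominance_maternal", None),
        ("low_parent_dominance_paternal", None),
        ("under_dominance", "under_dominance"),
        ("conserved", "conserved"),
    ]:
        if m is not None:
            n = int((mode == m).sum())
        else:
            base, side = label.rsplit("_", 1)
            n = int(((mode == base) & (parent == side)).sum())
        rows.append((label, n, _pct(n, non_additive)))
    rows.append(("unclassifiable", int((mode == "unclassifiable").sum()), np.nan))
    rows.append(("total_classified", classified, 100.0 if classified else np.nan))
    return pd.DataFrame(rows, columns=["class", "count", "percent"]).set_index("class")


def _pct(n: int, total: int) -> float:
    return 100.0 * n / total if total else float("nan")


def compare_stage_modes(
    calls_stage1: pd.DataFrame, calls_stage2: pd.DataFrame
) -> pd.DataFrame:
    """Contingency table of stage-1 mode vs stage-2 mode on shared genes."""
    shared = calls_stage1.index.intersection(calls_stage2.index)
    if len(shared) == 0:
        import warnings

        warnings.warn("no shared genes between stages", stacklevel=2)
        return pd.DataFrame()
    return pd.crosstab(
        calls_stage1.loc[shared, "mode"].rename("stage1"),
        calls_stage2.loc[shared, "mode"].rename("stage2"),
    )
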