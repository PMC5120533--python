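"""Mid-parent and best-parent heterosis statistics from trait means."""

from __future__ import annotations

import pandas as pd
from scipy import stats as _st

__all__ = ["mph", "bph", "heterosis_table", "welch_f1_vs_parent"]


def mph(p1_mean: float, p2_mean: float, f1_mean: float) -> float:
    """Mid-parent heterosis in percent: 100 * (F1 - MP) / MP with
    MP = (p1 + p2) / 2."""
    mid = (p1_mean + p2_mean) / 2.0
    if mid == 0:
        raise ValueError("mid-parent value is zero; MPH undefined")
    return 100.0 * (f1_mean - mid) / mid


def bph(
    p1_mean: float,
    p2_mean: float,
    f1_mean: float,
    higher_is_better: bool = True,
) -> float:
    """Best-parent heterosis in percent: 100 * (F1 - BP) / BP.

    BP is the larger parental mean when ``higher_is_better`` else the
    smaller one.
    """
    bp = max(p1_mean, p2_mean) if higher_is_better else min(p1_mean, p2_mean)
    if bp == 0:
        raise ValueError("best-parent value is zero; BPH undefined")
    return 100.0 * (f1_mean - bp) / bp


def heterosis_table(traits: pd.DataFrame) -> pd.DataFrame:
    """MPH/BPH per row of a trait-mean table.

    Expects columns p1_mean, p2_mean, f1_mean; optional higher_is_better
    (default True).  Returns the input with mph_pct and bph_pct appended.
    """
    out = traits.copy()
    hib = out.get("higher_is_better", pd.Series(True, index=out.index))
    out["mph_pct"] = [
        mph(r.p1_mean, r.p2_mean, r.f1_mean) for r in out.itertuples()
    ]
    out["bph_pct"] = [
        bph(r.p1_mean, r.p2_mean, r.f1_mean, bool(h))
        for r, h in zip(out.itertuples(), hib)
    ]
    return out


def welch_f1_vs_parent(
    f1_mean: float,
    f1_sd: float,
    f1_n: int,
    parent_mean: float,
    parent_sd: float,
    parent_n: int,
) -> float:
    """Welch two-sample t-test p-value (requires per-group n)."""
    res = _st.ttest_ind_from_stats(
        f1_mean, f1_sd, f1_n, parent_mean, parent_sd, parent_n, equal_var=False
    )
    return float(res.pvalue)
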