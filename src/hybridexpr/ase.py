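"""Allele-specific expression: SNP filtering, allelic-bias tests, gene calls.

Per-SNP allele counts in the hybrid are tested against a balanced 1:1
ratio with the two-sided binomial exact test; counts are summed per gene
for the gene-level call, and significantly biased genes are classified as
monoallelic (minor allele absent), preferential (>2-fold imbalance) or
biallelic (<=2-fold imbalance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hybridexpr.stats_core import DEFAULT_ALPHA, bh_adjust, binomial_two_sided

__all__ = [
    "SNP_COLUMNS",
    "GeneASECall",
    "read_snp_table",
    "filter_snps",
    "test_snp_bias",
    "aggregate_gene_ase",
    "classify_ase",
    "compare_stage_ase",
    "summarize_ase",
    "read_vcf_allele_counts",
]

SNP_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "gene_id",
    "maternal_hyb",
    "paternal_hyb",
    "maternal_parent_depth",
    "paternal_parent_depth",
    "base_quality_ok",
    "parental_consistent",
]

MIN_COVERAGE = 10
FOLD_BOUNDARY = 2.0
GENE_UNIVERSE = 39469


@dataclass
class GeneASECall:
    gene_id: str
    maternal_total: int
    paternal_total: int
    allelic_ratio: float
    p_value: float
    q_value: float
    bias: str  # maternal / paternal / none
    ase_class: str  # monoallelic / preferential / biallelic / unbiased


def read_snp_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    for col in ("base_quality_ok", "parental_consistent"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1", "t", "yes"))
    return df


def filter_snps(
    snps: pd.DataFrame, min_coverage: int = MIN_COVERAGE
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the SNP quality rules; return (retained, rejection_log).

    Rules, in order of reporting: base quality flag, parental-consistency
    flag, hybrid coverage >= ``min_coverage`` (inclusive).  The rejection
    log records the first rule that fired per dropped SNP.
    """
    coverage = snps["maternal_hyb"] + snps["paternal_hyb"]
    reasons = np.full(len(snps), "", dtype=object)
    bad_qual = ~snps["base_quality_ok"].to_numpy(bool)
    bad_cons = ~snps["parental_consistent"].to_numpy(bool)
    low_cov = (coverage < min_coverage).to_numpy()
    reasons[low_cov] = "coverage"
    reasons[bad_cons] = "parental_consistency"
    reasons[bad_qual] = "base_quality"
    dropped = reasons != ""
    log = pd.DataFrame(
        {"snp_id": snps.loc[dropped, "snp_id"], "reason": reasons[dropped]}
    )
    return snps.loc[~dropped].copy(), log.reset_index(drop=True)


def test_snp_bias(
    retained: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Per-SNP binomial test of the hybrid allele ratio against 0.5.

    Adds p_value and q_value (BH across all retained SNPs) columns.
    SNPs with zero coverage are untestable (p = NaN, excluded from BH).
    """
    out = retained.copy()
    m = out["maternal_hyb"].to_numpy(np.int64)
    p = out["paternal_hyb"].to_numpy(np.int64)
    cov = m + p
    pvals = np.full(len(out), np.nan)
    for i in range(len(out)):
        if cov[i] > 0:
            pvals[i] = binomial_two_sided(m[i], cov[i], 0.5)
    out["p_value"] = pvals
    qvals = np.full(len(out), np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        qvals[ok] = bh_adjust(pvals[ok])
    out["q_value"] = qvals
    out["significant"] = qvals < alpha
    return out


def aggregate_gene_ase(
    retained: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    fold_boundary: float = FOLD_BOUNDARY,
    mono_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Gene-level ASE calls from summed allele counts across a gene's SNPs.

    Returns a DataFrame indexed by gene with totals, pseudocounted
    allelic ratio, binomial p, BH q across genes, bias direction, and
    ase_class.
    """
    grouped = retained.groupby("gene_id")[["maternal_hyb", "paternal_hyb"]].sum()
    m = grouped["maternal_hyb"].to_numpy(np.int64)
    p = grouped["paternal_hyb"].to_numpy(np.int64)
    cov = m + p
    pvals = np.full(len(grouped), np.nan)
    for i in range(len(grouped)):
        if cov[i] > 0:
            pvals[i] = binomial_two_sided(m[i], cov[i], 0.5)
    out = pd.DataFrame(
        {
            "maternal_total": m,
            "paternal_total": p,
            "allelic_ratio": (m + 1) / (p + 1),
        },
        index=grouped.index,
    )
    out["p_value"] = pvals
    q = np.full(len(out), np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        q[ok] = bh_adjust(pvals[ok])
    out["q_value"] = q
    sig = q < alpha
    out["significant"] = sig
    out["bias"] = np.where(
        sig & (m > p), "maternal", np.where(sig & (p > m), "paternal", "none")
    )
    out["ase_class"] = [
        classify_ase(mi, pi, si, fold_boundary, mono_tolerance)
        for mi, pi, si in zip(m, p, sig)
    ]
    return out


def classify_ase(
    maternal_total: int,
    paternal_total: int,
    significant: bool,
    fold_boundary: float = FOLD_BOUNDARY,
    mono_tolerance: float = 0.0,
) -> str:
    """Bias class for one gene.

    unbiased if the gene-level test is not significant; monoallelic if the
    minor allele's share is <= ``mono_tolerance`` (default: strictly zero
    reads); preferential if the major/minor ratio exceeds
    ``fold_boundary`` (a ratio of exactly 2 is biallelic); else biallelic.
    """
    if not significant:
        return "unbiased"
    major = max(maternal_total, paternal_total)
    minor = min(maternal_total, paternal_total)
    total = major + minor
    if total == 0:
        return "unbiased"
    if minor <= mono_tolerance * total:
        return "monoallelic"
    if major / minor > fold_boundary:
        return "preferential"
    return "biallelic"


def compare_stage_ase(
    calls_stage1: pd.DataFrame, calls_stage2: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene bias transitions between stages on the shared gene set.

    Labels: conserved (same bias both stages, including none/none),
    switched (maternal <-> paternal), lost (biased -> none), gained
    (none -> biased).
    """
    shared = calls_stage1.index.intersection(calls_stage2.index)
    if len(shared) == 0:
        import warnings

        warnings.warn("no shared genes between stages", stacklevel=2)
        return pd.DataFrame(columns=["bias_stage1", "bias_stage2", "transition"])
    b1 = calls_stage1.loc[shared, "bias"]
    b2 = calls_stage2.loc[shared, "bias"]
    transition = np.where(
        b1 == b2,
        "conserved",
        np.where(
            b1 == "none", "gained", np.where(b2 == "none", "lost", "switched")
        ),
    )
    return pd.DataFrame(
        {"bias_stage1": b1, "bias_stage2": b2, "transition": transition},
        index=shared,
    )


def summarize_ase(
    retained_snps: pd.DataFrame,
    gene_calls: pd.DataFrame,
    gene_universe: int = GENE_UNIVERSE,
) -> pd.Series:
    """Table-4-shaped summary of the ASE input after filtering."""
    n_snps = len(retained_snps)
    reads = int(
        (retained_snps["maternal_hyb"] + retained_snps["paternal_hyb"]).sum()
    )
    n_genes = len(gene_calls)
    n_biased = int((gene_calls["bias"] != "none").sum())
    n_maternal = int((gene_calls["bias"] == "maternal").sum())
    n_paternal = int((gene_calls["bias"] == "paternal").sum())
    return pd.Series(
        {
            "snps": n_snps,
            "reads_covering_snps": reads,
            "reads_per_snp": reads / n_snps if n_snps else float("nan"),
            "genes": n_genes,
            "snps_per_gene": n_snps / n_genes if n_genes else float("nan"),
            "pct_of_protein_coding": _pct(n_genes, gene_universe),
            "biased_genes": n_biased,
            "pct_biased": _pct(n_biased, n_genes),
            "maternal_biased": n_maternal,
            "pct_maternal_of_biased": _pct(n_maternal, n_biased),
            "paternal_biased": n_paternal,
            "pct_paternal_of_biased": _pct(n_paternal, n_biased),
        }
    )


def _pct(n: int, total: int) -> float:
    return 100.0 * n / total if total else float("nan")


def read_vcf_allele_counts(
    vcf_path: str,
    gene_map: pd.DataFrame,
    maternal_sample: str,
    paternal_sample: str,
    hybrid_sample: str,
    min_qual: float = 20.0,
) -> pd.DataFrame:
    """Build the SNP allele-count table from a VCF with per-sample AD fields.

    ``gene_map`` is a BED-like frame with columns chrom, start, end,
    gene_id (start 0-based, end exclusive).  A site is parentally
    consistent when each parent is homozygous for a different allele; the
    hybrid's AD entries for the two parental alleles give the maternal
    and paternal counts.  ``base_quality_ok`` is derived from site QUAL.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    idx = {}
    for name in (maternal_sample, paternal_sample, hybrid_sample):
        if name not in samples:
            raise ValueError(f"sample {name!r} not in VCF (has {samples})")
        idx[name] = samples.index(name)
    records = []
    for var in vcf:
        if var.ALT is None or len(var.ALT) == 0:
            continue
        gts = var.genotypes  # [allele1, allele2, phased]
        ad = var.format("AD")
        if ad is None:
            continue
        gm = gts[idx[maternal_sample]][:2]
        gp = gts[idx[paternal_sample]][:2]
        consistent = (
            gm[0] == gm[1] and gp[0] == gp[1] and gm[0] != gp[0]
            and gm[0] >= 0 and gp[0] >= 0
        )
        mat_allele = gm[0] if gm[0] >= 0 else 0
        pat_allele = gp[0] if gp[0] >= 0 else 1
        hyb_ad = ad[idx[hybrid_sample]]
        mat_hyb = int(hyb_ad[mat_allele]) if consistent else 0
        pat_hyb = int(hyb_ad[pat_allele]) if consistent else 0
        records.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "maternal_hyb": max(mat_hyb, 0),
                "paternal_hyb": max(pat_hyb, 0),
                "maternal_parent_depth": int(max(ad[idx[maternal_sample]].sum(), 0)),
                "paternal_parent_depth": int(max(ad[idx[paternal_sample]].sum(), 0)),
                "base_quality_ok": bool(
                    var.QUAL is not None and var.QUAL >= min_qual
                ),
                "parental_consistent": bool(consistent),
            }
        )
    df = pd.DataFrame(records)
    if df.empty:
        return pd.DataFrame(columns=SNP_COLUMNS)
    df["gene_id"] = _assign_genes(df, gene_map)
    df = df.dropna(subset=["gene_id"])
    return df[SNP_COLUMNS].reset_index(drop=True)


def _assign_genes(snps: pd.DataFrame, gene_map: pd.DataFrame) -> pd.Series:
    """Map 1-based SNP positions onto BED intervals (first hit wins)."""
    assigned = pd.Series(np.nan, index=snps.index, dtype=object)
    for chrom, sub in gene_map.groupby("chrom"):
        on_chrom = snps["chrom"] == chrom
        if not on_chrom.any():
            continue
        pos0 = snps.loc[on_chrom, "pos"] - 1  # BED is 0-based
        for row in sub.itertuples():
            hit = on_chrom & (snps["pos"] - 1 >= row.start) & (snps["pos"] - 1 < row.end)
            assigned[hit & assigned.isna()] = row.gene_id
        del pos0
    return assigned
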