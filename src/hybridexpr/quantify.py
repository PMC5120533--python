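"""RPKM quantification, expression flags, and expression-level bins."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionRecord",
    "compute_rpkm",
    "flag_expressed",
    "bin_expression_level",
    "rpkm_matrix",
    "expression_table",
    "gene_lengths_from_gff3",
    "read_counts_tsv",
    "read_lengths_tsv",
    "read_design_tsv",
]

RPKM_EXPRESSED = 1.0
BIN_MEDIUM = 20.0
BIN_HIGH = 50.0

LEVEL_BINS = ("high", "medium", "low", "not_expressed")


@dataclass
class ExpressionRecord:
    gene_id: str
    length_bp: int
    counts: dict
    rpkm: dict
    expressed: bool
    level_bin: str


def compute_rpkm(count: float, length_bp: int, library_size: int) -> float:
    """RPKM = 1e9 * count / (length_bp * library_size)."""
    if length_bp <= 0:
        raise ValueError(f"length_bp must be positive, got {length_bp}")
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return 1e9 * count / (length_bp * library_size)


def flag_expressed(rpkms: Iterable[float], threshold: float = RPKM_EXPRESSED) -> bool:
    """A gene is expressed iff RPKM >= threshold in at least one genotype."""
    values = list(rpkms)
    if not values:
        raise ValueError("flag_expressed requires at least one RPKM value")
    return max(values) >= threshold


def bin_expression_level(rpkm: float) -> str:
    """Assign one of {high, medium, low, not_expressed}.

    high: rpkm >= 50; medium: 20 <= rpkm < 50; low: 1 <= rpkm < 20;
    not_expressed: rpkm < 1.  Bins partition [0, inf); both lower bounds
    are inclusive.
    """
    if rpkm < 0:
        raise ValueError(f"rpkm must be non-negative, got {rpkm}")
    if rpkm >= BIN_HIGH:
        return "high"
    if rpkm >= BIN_MEDIUM:
        return "medium"
    if rpkm >= RPKM_EXPRESSED:
        return "low"
    return "not_expressed"


def rpkm_matrix(
    counts: pd.DataFrame,
    lengths: Mapping[str, int] | pd.Series,
    library_sizes: Mapping[str, int] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample RPKM for a genes x samples count matrix.

    ``library_sizes`` defaults to the per-sample total of gene-assigned
    reads (column sums of ``counts``).
    """
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths for {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("all gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lib = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if (lib <= 0).any():
        raise ValueError("all library sizes must be positive")
    return 1e9 * counts.div(lengths, axis=0).div(lib, axis=1)


def expression_table(
    counts: pd.DataFrame,
    lengths: Mapping[str, int] | pd.Series,
    design: pd.DataFrame,
    threshold: float = RPKM_EXPRESSED,
) -> pd.DataFrame:
    """Per-gene expression summary across genotypes.

    A genotype's RPKM is the mean of its replicate RPKMs; the expressed
    flag requires RPKM >= threshold in at least one genotype, and the
    level bin is taken from the maximal genotype RPKM.

    ``design`` maps sample -> genotype (index: sample IDs matching the
    count matrix columns; column ``genotype``).
    """
    _check_design(design, counts.columns)
    rpkm = rpkm_matrix(counts, lengths)
    geno = design["genotype"]
    geno_rpkm = rpkm.T.groupby(geno).mean().T
    geno_rpkm.columns = [f"rpkm_{g}" for g in geno_rpkm.columns]
    out = geno_rpkm.copy()
    max_rpkm = geno_rpkm.max(axis=1)
    out["expressed"] = max_rpkm >= threshold
    out["level_bin"] = [bin_expression_level(v) for v in max_rpkm]
    return out


def _check_design(design: pd.DataFrame, samples: Sequence[str]) -> None:
    if "genotype" not in design.columns:
        raise ValueError("design table must have a 'genotype' column")
    missing = [s for s in samples if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design table: {missing}")


def gene_lengths_from_gff3(path: str, feature: str = "exon") -> pd.Series:
    """Exonic-union gene length (bp) per gene from a GFF3 file.

    The length of a gene is the number of bases covered by the union of
    its ``feature`` intervals (1-based inclusive coordinates).  Features
    are attributed to genes via the Parent/ID attribute chain.
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    lengths: dict[str, int] = {}
    for gene in db.features_of_type("gene"):
        intervals = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype=feature)
        )
        if not intervals:
            intervals = [(gene.start, gene.end)]
        total = 0
        cur_s, cur_e = intervals[0]
        for s, e in intervals[1:]:
            if s > cur_e + 1:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s + 1
        lengths[gene.id] = total
    return pd.Series(lengths, name="length_bp", dtype=int)


def read_counts_tsv(path: str) -> pd.DataFrame:
    """Genes x samples integer count matrix from TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.astype(np.int64)


def read_lengths_tsv(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.iloc[:, 0].astype(int).rename("length_bp")


def read_design_tsv(path: str) -> pd.DataFrame:
    """Sample design table: index sample, columns genotype/stage/replicate."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
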