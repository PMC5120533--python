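"""Seeded synthetic data with known truth for every pipeline stage.

Two generators: :func:`simulate_counts` draws negative-binomial gene
counts for two inbred parents and their F1 across replicates, with the
hybrid mean set by a configurable inheritance mode per gene;
:func:`simulate_ase` draws per-SNP allele counts in the hybrid plus
parental site depths whose ratios encode configurable cis (B) and trans
(A - B) effects.  All randomness flows through one seeded generator, so
identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "simulate_counts",
    "simulate_ase",
    "counts_for_ase_truth",
    "MODE_NAMES",
    "REG_NAMES",
]

MODE_NAMES = (
    "additive",
    "over",
    "under",
    "hp_dom_p1",
    "hp_dom_p2",
    "lp_dom_p1",
    "lp_dom_p2",
    "conserved",
    "null",
)

REG_NAMES = ("cis_only", "trans_only", "cis_trans_enh", "cis_trans_comp", "conserved")

#: mode name -> classifier mode it should be recovered as
TRUE_MODE_LABEL = {
    "additive": "additive",
    "over": "over_dominance",
    "under": "under_dominance",
    "hp_dom_p1": "high_parent_dominance",
    "hp_dom_p2": "high_parent_dominance",
    "lp_dom_p1": "low_parent_dominance",
    "lp_dom_p2": "low_parent_dominance",
    "conserved": "conserved",
    "null": "additive",
}

TRUE_CATEGORY_LABEL = {
    "cis_only": "cis_only",
    "trans_only": "trans_only",
    "cis_trans_enh": "cis_trans",
    "cis_trans_comp": "cis_trans",
    "conserved": "conserved",
}


def _default_mode_proportions() -> dict[str, float]:
    # Balanced so the three genotypes have equal expected library totals:
    # over-dominance inflates the F1 library, under-dominance and the
    # below-mid-parent conserved placement deflate it, and the dominance
    # classes cancel pairwise.  Unequal totals would otherwise shift every
    # rate comparison for high-count genes (compositional bias).
    return {
        "additive": 0.30,
        "over": 0.035,
        "under": 0.035,
        "hp_dom_p1": 0.075,
        "hp_dom_p2": 0.075,
        "lp_dom_p1": 0.075,
        "lp_dom_p2": 0.075,
        "conserved": 0.10,
        "null": 0.23,
    }


def _default_reg_proportions() -> dict[str, float]:
    return {
        "cis_only": 0.30,
        "trans_only": 0.15,
        "cis_trans_enh": 0.10,
        "cis_trans_comp": 0.10,
        "conserved": 0.35,
    }


@dataclass
class SimConfig:
    n_genes: int = 2000
    replicates: int = 2
    mode_proportions: dict = field(default_factory=_default_mode_proportions)
    reg_proportions: dict = field(default_factory=_default_reg_proportions)
    effect_log2_min: float = 1.0
    effect_log2_max: float = 4.0
    base_mean_median: float = 200.0
    base_mean_sigma: float = 0.8  # lognormal sigma (natural log scale)
    dispersion: float = 0.05  # NB: var = mu + dispersion * mu^2
    snps_per_gene_mean: float = 3.5  # shifted Poisson, min 1
    site_coverage_mean: float = 70.0
    site_coverage_dispersion: float = 0.1
    length_min: int = 500
    length_max: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, props, names in (
            ("mode_proportions", self.mode_proportions, MODE_NAMES),
            ("reg_proportions", self.reg_proportions, REG_NAMES),
        ):
            unknown = set(props) - set(names)
            if unknown:
                raise ValueError(f"{name}: unknown keys {sorted(unknown)}")
            total = sum(props.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(v < 0 for v in props.values()):
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "n_genes",
            "replicates",
            "effect_log2_min",
            "effect_log2_max",
            "base_mean_median",
            "base_mean_sigma",
            "snps_per_gene_mean",
            "site_coverage_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Negative-binomial counts with var = mu + dispersion * mu^2.

    Falls back to Poisson when dispersion is (numerically) zero.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _draw_modes(rng, proportions: dict, names, n: int) -> np.ndarray:
    labels = [k for k in names if proportions.get(k, 0) > 0]
    probs = np.array([proportions[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=n, p=probs)


def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (counts, design, truth) for P1/P2/F1 x replicates.

    Per gene the parental means are set symmetrically around a lognormal
    base mean at log2 distance ``effect_log2``; the F1 mean follows the
    gene's true mode: additive -> mid-parent; dominance -> the matching
    parent's mean; over -> 2x the high parent; under -> 0.5x the low
    parent; conserved -> inside the parental range one quarter of the way
    up from the low parent (log scale); null -> no divergence anywhere.

    The truth table carries gene lengths (for RPKM) and the classifier
    label each gene should be recovered as.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    modes = _draw_modes(rng, cfg.mode_proportions, MODE_NAMES, cfg.n_genes)
    base = cfg.base_mean_median * np.exp(
        rng.normal(0.0, cfg.base_mean_sigma, cfg.n_genes)
    )
    effect = rng.uniform(cfg.effect_log2_min, cfg.effect_log2_max, cfg.n_genes)
    sign = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    lengths = rng.integers(cfg.length_min, cfg.length_max + 1, cfg.n_genes)

    mu1 = np.empty(cfg.n_genes)
    mu2 = np.empty(cfg.n_genes)
    muf = np.empty(cfg.n_genes)
    for i, mode in enumerate(modes):
        e = effect[i]
        if mode == "null":
            effect[i] = 0.0
            mu1[i] = mu2[i] = muf[i] = base[i]
            continue
        if mode in ("hp_dom_p1", "lp_dom_p2"):
            s = 1.0  # P1 is the high parent
        elif mode in ("hp_dom_p2", "lp_dom_p1"):
            s = -1.0
        else:
            s = sign[i]
        mu1[i] = base[i] * 2.0 ** (s * e / 2.0)
        mu2[i] = base[i] * 2.0 ** (-s * e / 2.0)
        lo, hi = min(mu1[i], mu2[i]), max(mu1[i], mu2[i])
        if mode == "additive":
            muf[i] = (mu1[i] + mu2[i]) / 2.0
        elif mode == "over":
            muf[i] = 2.0 * hi
        elif mode == "under":
            muf[i] = 0.5 * lo
        elif mode in ("hp_dom_p1", "hp_dom_p2"):
            muf[i] = hi
        elif mode in ("lp_dom_p1", "lp_dom_p2"):
            muf[i] = lo
        elif mode == "conserved":
            muf[i] = lo * 2.0 ** (e / 4.0)

    data = {}
    design_rows = []
    for geno, mu in (("P1", mu1), ("P2", mu2), ("F1", muf)):
        for rep in range(1, cfg.replicates + 1):
            sample = f"{geno}_r{rep}"
            data[sample] = _nb_draw(rng, mu, cfg.dispersion)
            design_rows.append({"sample": sample, "genotype": geno, "replicate": rep})
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    design = pd.DataFrame(design_rows).set_index("sample")
    truth = pd.DataFrame(
        {
            "true_mode": [TRUE_MODE_LABEL[m] for m in modes],
            "sim_mode": modes,
            "effect_log2": effect,
            "mu_p1": mu1,
            "mu_p2": mu2,
            "mu_f1": muf,
            "length_bp": lengths,
        },
        index=counts.index,
    )
    return counts, design, truth


def simulate_ase(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (snp_table, truth) encoding cis/trans effects.

    Per gene: true_A is the parental log2 divergence, true_B the hybrid
    allelic log2 divergence.  cis_only: B = A; trans_only: B = 0;
    cis_trans: B = +/- u*A with u ~ U(0.25, 0.75), the sign chosen so the
    interaction is enhancing (same direction as A) or compensating;
    conserved: A = B = 0.  Hybrid maternal counts per SNP are binomial at
    fraction 2^B / (1 + 2^B); parental site depths are split binomially
    at fraction 2^A / (1 + 2^A).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    cats = _draw_modes(rng, cfg.reg_proportions, REG_NAMES, cfg.n_genes)
    magnitude = rng.uniform(cfg.effect_log2_min, cfg.effect_log2_max, cfg.n_genes)
    sign = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    u = rng.uniform(0.25, 0.75, cfg.n_genes)

    A = np.where(cats == "conserved", 0.0, sign * magnitude)
    B = np.select(
        [
            cats == "cis_only",
            cats == "trans_only",
            cats == "cis_trans_enh",
            cats == "cis_trans_comp",
        ],
        [A, 0.0, A * u, -A * u],
        default=0.0,
    )
    interaction = np.select(
        [cats == "cis_trans_enh", cats == "cis_trans_comp"],
        ["enhancing", "compensating"],
        default="none",
    )

    n_snps = rng.poisson(cfg.snps_per_gene_mean - 1.0, cfg.n_genes) + 1
    rows = []
    frac_b = 2.0**B / (1.0 + 2.0**B)
    frac_a = 2.0**A / (1.0 + 2.0**A)
    for i, gene in enumerate(genes):
        for j in range(n_snps[i]):
            cov = int(
                _nb_draw(
                    rng, cfg.site_coverage_mean, cfg.site_coverage_dispersion
                )
            )
            mat = int(rng.binomial(cov, frac_b[i])) if cov > 0 else 0
            parent_total = int(
                _nb_draw(
                    rng, 2.0 * cfg.site_coverage_mean, cfg.site_coverage_dispersion
                )
            )
            mat_parent = (
                int(rng.binomial(parent_total, frac_a[i])) if parent_total > 0 else 0
            )
            rows.append(
                {
                    "snp_id": f"{gene}_snp{j}",
                    "chrom": "chr1",
                    "pos": i * 10000 + j * 100 + 1,
                    "gene_id": gene,
                    "maternal_hyb": mat,
                    "paternal_hyb": cov - mat,
                    "maternal_parent_depth": mat_parent,
                    "paternal_parent_depth": parent_total - mat_parent,
                    "base_quality_ok": True,
                    "parental_consistent": True,
                }
            )
    snp_table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "true_category": [TRUE_CATEGORY_LABEL[c] for c in cats],
            "sim_category": cats,
            "true_A": A,
            "true_B": B,
            "true_interaction": interaction,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return snp_table, truth


def counts_for_ase_truth(
    truth: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count matrix matching an ASE truth table, with additive hybrids.

    Parental means are placed at log2 distance |true_A| (parent 1 higher
    when true_A > 0) and the F1 mean at the mid-parent value, so genes
    generated as pure-cis should be recovered as additive by the
    inheritance classifier.  Returns (counts, design).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = len(truth)
    base = cfg.base_mean_median * np.exp(rng.normal(0.0, cfg.base_mean_sigma, n))
    a = truth["true_A"].to_numpy(float)
    mu1 = base * 2.0 ** (a / 2.0)
    mu2 = base * 2.0 ** (-a / 2.0)
    muf = (mu1 + mu2) / 2.0
    data = {}
    design_rows = []
    for geno, mu in (("P1", mu1), ("P2", mu2), ("F1", muf)):
        for rep in range(1, cfg.replicates + 1):
            sample = f"{geno}_r{rep}"
            data[sample] = _nb_draw(rng, mu, cfg.dispersion)
            design_rows.append({"sample": sample, "genotype": geno, "replicate": rep})
    counts = pd.DataFrame(data, index=truth.index)
    design = pd.DataFrame(design_rows).set_index("sample")
    return counts, design
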