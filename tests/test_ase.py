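import numpy as np
import pandas as pd
import pytest

from hybridexpr import ase
from hybridexpr.stats_core import binomial_two_sided


def _snp_frame(rows):
    base = {
        "chrom": "chr1",
        "pos": 100,
        "gene_id": "gA",
        "maternal_parent_depth": 50,
        "paternal_parent_depth": 50,
        "base_quality_ok": True,
        "parental_consistent": True,
    }
    recs = []
    for i, row in enumerate(rows):
        rec = dict(base, snp_id=f"s{i}", **row)
        recs.append(rec)
    return pd.DataFrame(recs)


class TestFilterSnps:
    def test_coverage_rule(self):
        snps = _snp_frame([{"maternal_hyb": 4, "paternal_hyb": 5}])
        retained, log = ase.filter_snps(snps)
        assert retained.empty
        assert list(log["reason"]) == ["coverage"]

    def test_quality_rule(self):
        snps = _snp_frame(
            [{"maternal_hyb": 5, "paternal_hyb": 5, "base_quality_ok": False}]
        )
        retained, log = ase.filter_snps(snps)
        assert retained.empty
        assert list(log["reason"]) == ["base_quality"]

    def test_consistency_rule(self):
        snps = _snp_frame(
            [{"maternal_hyb": 5, "paternal_hyb": 5, "parental_consistent": False}]
        )
        _, log = ase.filter_snps(snps)
        assert list(log["reason"]) == ["parental_consistency"]

    def test_boundary_inclusive(self):
        snps = _snp_frame([{"maternal_hyb": 5, "paternal_hyb": 5}])
        retained, log = ase.filter_snps(snps)
        assert len(retained) == 1 and log.empty


class TestSnpBias:
    def test_balanced(self):
        snps = _snp_frame([{"maternal_hyb": 5, "paternal_hyb": 5}])
        out = ase.test_snp_bias(snps)
        assert out["p_value"].iloc[0] == 1.0

    def test_extreme(self):
        snps = _snp_frame([{"maternal_hyb": 0, "paternal_hyb": 10}])
        out = ase.test_snp_bias(snps)
        assert out["p_value"].iloc[0] == pytest.approx(2 / 1024)

    def test_matches_enumeration_at_n40(self):
        snps = _snp_frame([{"maternal_hyb": 30, "paternal_hyb": 10}])
        out = ase.test_snp_bias(snps)
        assert out["p_value"].iloc[0] == pytest.approx(binomial_two_sided(30, 40, 0.5))


class TestAggregateGeneAse:
    def test_sums_and_bias(self):
        snps = _snp_frame(
            [
                {"maternal_hyb": 10, "paternal_hyb": 0},
                {"maternal_hyb": 8, "paternal_hyb": 2},
            ]
        )
        genes = ase.aggregate_gene_ase(snps)
        row = genes.loc["gA"]
        assert (row["maternal_total"], row["paternal_total"]) == (18, 2)
        assert row["p_value"] == pytest.approx(binomial_two_sided(18, 20, 0.5))
        assert row["bias"] == "maternal"

    def test_single_balanced_snp_unbiased(self):
        snps = _snp_frame([{"maternal_hyb": 7, "paternal_hyb": 7}])
        genes = ase.aggregate_gene_ase(snps)
        assert genes.loc["gA", "bias"] == "none"
        assert genes.loc["gA", "ase_class"] == "unbiased"

    def test_discordant_snps_cancel(self):
        snps = _snp_frame(
            [
                {"maternal_hyb": 10, "paternal_hyb": 0},
                {"maternal_hyb": 0, "paternal_hyb": 10},
            ]
        )
        genes = ase.aggregate_gene_ase(snps)
        assert genes.loc["gA", "bias"] == "none"

    def test_invariant_to_read_distribution(self):
        a = _snp_frame([{"maternal_hyb": 30, "paternal_hyb": 10}])
        b = _snp_frame(
            [
                {"maternal_hyb": 15, "paternal_hyb": 5},
                {"maternal_hyb": 15, "paternal_hyb": 5},
            ]
        )
        pa = ase.aggregate_gene_ase(a).loc["gA", "p_value"]
        pb = ase.aggregate_gene_ase(b).loc["gA", "p_value"]
        assert pa == pytest.approx(pb)


class TestClassifyAse:
    def test_monoallelic(self):
        assert ase.classify_ase(300, 0, True) == "monoallelic"

    def test_preferential(self):
        assert ase.classify_ase(400, 100, True) == "preferential"

    def test_biallelic(self):
        assert ase.classify_ase(300, 200, True) == "biallelic"
        # ratio 1.5 really is significant at these totals
        assert binomial_two_sided(300, 500, 0.5) < 0.05

    def test_exact_twofold_is_biallelic(self):
        assert ase.classify_ase(200, 100, True) == "biallelic"

    def test_not_significant_is_unbiased(self):
        assert ase.classify_ase(300, 0, False) == "unbiased"


class TestLabelSwapSymmetry:
    def test_swap_flips_bias_preserves_p(self, small_ase_sim):
        _, snps, _ = small_ase_sim
        retained, _ = ase.filter_snps(snps)
        swapped = retained.rename(
            columns={
                "maternal_hyb": "paternal_hyb",
                "paternal_hyb": "maternal_hyb",
                "maternal_parent_depth": "paternal_parent_depth",
                "paternal_parent_depth": "maternal_parent_depth",
            }
        )
        g1 = ase.aggregate_gene_ase(retained)
        g2 = ase.aggregate_gene_ase(swapped)
        assert np.allclose(g1["p_value"], g2["p_value"], equal_nan=True)
        flip = {"maternal": "paternal", "paternal": "maternal", "none": "none"}
        assert (g2["bias"] == g1["bias"].map(flip)).all()
        assert g1["ase_class"].value_counts().equals(g2["ase_class"].value_counts())


class TestCompareStageAse:
    def _calls(self, biases, genes):
        return pd.DataFrame({"bias": biases}, index=genes)

    def test_identical(self):
        c = self._calls(["maternal", "none"], ["a", "b"])
        out = ase.compare_stage_ase(c, c)
        assert (out["transition"] == "conserved").all()

    def test_printed_ratio(self):
        # 7261 of 10388 shared genes conserved -> 69.9%
        assert 100 * 7261 / 10388 == pytest.approx(69.9, abs=0.05)

    def test_resampled_conservation(self):
        rng = np.random.default_rng(13)
        n = 4000
        genes = [f"g{i}" for i in range(n)]
        b1 = rng.choice(["maternal", "paternal"], size=n)
        b2 = b1.copy()
        flip = rng.random(n) < 0.25
        b2[flip] = np.where(b1[flip] == "maternal", "paternal", "maternal")
        out = ase.compare_stage_ase(self._calls(b1, genes), self._calls(b2, genes))
        conserved = (out["transition"] == "conserved").mean()
        assert conserved == pytest.approx(0.75, abs=0.03)


class TestSummarizeAse:
    def test_table_shape_values(self, small_ase_sim):
        _, snps, _ = small_ase_sim
        retained, _ = ase.filter_snps(snps)
        genes = ase.aggregate_gene_ase(retained)
        summary = ase.summarize_ase(retained, genes, gene_universe=39469)
        assert summary["snps"] == len(retained)
        assert summary["reads_per_snp"] == pytest.approx(
            (retained["maternal_hyb"] + retained["paternal_hyb"]).sum() / len(retained)
        )
        assert summary["pct_of_protein_coding"] == pytest.approx(
            100 * len(genes) / 39469
        )


class TestVcfInput:
    def test_read_vcf_allele_counts(self, tmp_path):
        pytest.importorskip("cyvcf2")
        vcf = tmp_path / "snps.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
            "##contig=<ID=chr1,length=100000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tMOM\tDAD\tHYB\n"
            "chr1\t150\tsnp1\tA\tG\t60\tPASS\t.\tGT:AD\t0/0:30,0\t1/1:0,25\t0/1:12,8\n"
            "chr1\t250\tsnp2\tC\tT\t10\tPASS\t.\tGT:AD\t0/0:30,0\t1/1:0,25\t0/1:6,14\n"
            "chr1\t950\tsnp3\tG\tA\t60\tPASS\t.\tGT:AD\t0/1:15,15\t1/1:0,25\t0/1:9,11\n"
        )
        gene_map = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [500], "gene_id": ["gX"]}
        )
        df = ase.read_vcf_allele_counts(str(vcf), gene_map, "MOM", "DAD", "HYB")
        assert list(df["snp_id"]) == ["snp1", "snp2"]  # snp3 outside gene
        row = df.set_index("snp_id").loc["snp1"]
        assert (row["maternal_hyb"], row["paternal_hyb"]) == (12, 8)
        assert row["base_quality_ok"]
        assert row["parental_consistent"]
        row2 = df.set_index("snp_id").loc["snp2"]
        assert not row2["base_quality_ok"]  # QUAL 10 < 20
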