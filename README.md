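# hybridexpr

Hybrid-vs-parent transcriptome analysis for an F1 hybrid and its two inbred
parents, exercised end-to-end on synthetic data with known truth:

- **quantify** — RPKM from gene-level read counts, expression flags
  (RPKM ≥ 1 in at least one genotype) and level bins (high ≥ 50,
  medium 20–50, low 1–20).
- **diffexpr** — pairwise differential expression via Fisher's exact test on
  library-equalized pooled counts, BH-adjusted, with Up/Down/Total summaries
  and Venn overlaps.
- **inheritance** — per-gene inheritance mode against the mid-parent value:
  additive, over-/under-dominance, high-/low-parent dominance (with the
  dominant parent recorded), conserved, unclassifiable; cross-stage
  persistence tables.
- **ase** — SNP filtering (quality, parental consistency, coverage ≥ 10),
  per-SNP and gene-level allelic-bias binomial tests, and bias classes
  (monoallelic / preferential / biallelic / unbiased); TSV or VCF+AD input.
- **cistrans** — decomposition of parental divergence (A) into cis (B, hybrid
  allelic imbalance) and trans (A − B) components; six-way categories with
  the enhancing/compensating split, percent-cis binning, and the
  regulation × inheritance cross-tabulation.
- **heterosis** — mid-parent and best-parent heterosis percentages from trait
  means.
- **simulate** — seeded negative-binomial count simulator and SNP
  allele-count simulator with configurable inheritance modes and cis/trans
  effects, used as ground truth throughout the test suite.
- **stats_core** — the shared exact-test primitives (two-sided binomial,
  Fisher 2×2, BH FDR), validated against brute-force enumeration oracles.

## CLI

```sh
hybridexpr simulate --out sim/ --seed 1 --n-genes 2000
hybridexpr quantify --counts sim/counts.tsv --lengths sim/lengths.tsv --design sim/design.tsv --out expr.tsv
hybridexpr de       --counts sim/counts.tsv --design sim/design.tsv --comparisons P1:P2,F1:P1,F1:P2 --out de
hybridexpr inherit  --counts sim/counts.tsv --design sim/design.tsv --out inh
hybridexpr ase      --snps sim/snps.tsv --out ase
hybridexpr cistrans --snps sim/snps.tsv --out ct
hybridexpr heterosis --traits traits.tsv --out het.tsv
hybridexpr run --config pipeline.yaml       # all stages from one YAML
```

All tables are TSV with a `#`-prefixed provenance header (version, seed,
config hash). A pipeline run is a pure function of (inputs, config, seed):
reruns are byte-identical.

Example `pipeline.yaml`:

```yaml
stages: [simulate, quantify, de, inherit, ase, cistrans]
seed: 1
alpha: 0.05
outdir: run1
simulate: {n_genes: 2000}
```

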