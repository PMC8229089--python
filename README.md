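# methmr

Summary-statistics Mendelian randomization for methylation–phenotype
integration, exercised entirely on synthetic data with known causal ground
truth.

Given mQTL/eQTL summary statistics, GWAS summary statistics and an LD
reference panel, the pipeline identifies methylation probes whose signal is
consistent with a causal effect on the phenotype:

1. **Colocalization** — SMR test at the top cis-QTL SNP
   (`T = z₁²z₂²/(z₁²+z₂²)`, χ²(1)) plus the HEIDI heterogeneity test, whose
   null is a single shared causal variant; rejection indicates linkage of
   distinct variants. The weighted-χ² mixture p-value is evaluated by
   Imhof's method with a Satterthwaite fallback.
2. **Forward MR** — instruments are exposure-significant SNPs (p < 5e-8)
   greedily pruned to pairwise r² < 0.05; the causal effect is the GLS
   combination of per-SNP Wald ratios with delta-method variances and
   LD-induced covariances; pleiotropic outliers (heterogeneity p < 0.01
   against a provisional fit) are removed in a single pass.
3. **Reverse-causation filter** — the same machinery with exposure and
   outcome swapped; pairs with reverse p < 0.05 are excluded.
4. **Mediation** — methylation → expression and expression → phenotype MR
   chains with sign-consistency against the direct effect.
5. **Rare-variant matching** — positional overlap of a variant table with
   significant mQTLs (exact position or within a window).

The `simulate` module generates two-sample cohorts (disjoint exposure and
outcome samples plus an LD panel) under five scenarios — `causal`,
`pleiotropy`, `linkage`, `reverse`, `null` — with block-decaying LD from a
latent-Gaussian AR(1) haplotype model, and emits `.ma`/QTL/panel/truth files.

## CLI

```bash
# synthetic data: a single scenario or the 50-probe mixed fixture
methmr simulate --scenario fixture --seed 2 --out data/

# per-stage commands
methmr coloc --qtl data/mqtl.tsv --gwas data/gwas.ma --ld-panel data/panel.tsv \
             --p-smr 5e-8 --p-heidi 0.05 --out coloc.tsv
methmr mr --exposure data/mqtl.tsv --outcome data/gwas.ma \
          --ld-panel data/panel.tsv --out mr.tsv --plot plots/
methmr mediate --mqtl data/mqtl.tsv --eqtl data/eqtl.tsv \
               --gwas data/gwas.ma --ld-panel data/panel.tsv --out med.tsv
methmr rare-overlap --variants data/rare_variants.tsv --mqtl data/mqtl.tsv \
                    --window 1000 --out overlap.tsv

# full discovery (+ optional replication) cascade from a YAML config
methmr pipeline --config config.yaml
```

A minimal `config.yaml`:

```yaml
mqtl: data/mqtl.tsv
gwas: data/gwas.ma
panel: data/panel.tsv
eqtl: data/eqtl.tsv          # optional
variants: data/rare_variants.tsv  # optional
out_dir: out/
p_smr: 5.0e-8
p_heidi_keep: 0.05
p_forward: 5.0e-8
p_reverse: 0.05
```

## File formats

All plain text, whitespace/tab-delimited with a header:

- `.ma` summary statistics: `SNP A1 A2 freq b se p N`
- QTL tables: `Probe ProbeChr ProbePos SNP Chr Pos A1 A2 freq b se p N`
- LD panel: first column `IID`, then one column per SNP headed `snpid:A1:A2`
  with effect-allele dosages in [0, 2]
- rare variants: `variant_id chrom pos ref alt condition`

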