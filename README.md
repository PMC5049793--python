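# cpmeta

Cross-phenotype meta-analysis of GWAS summary statistics from multiple
cohort × trait panels whose test statistics are correlated (overlapping or
related samples, correlated traits).

Given per-panel summary statistics (SNP, alleles, beta, SE, P, N), the
package:

1. **ingests and harmonizes** the panels onto a shared per-SNP reference
   effect allele (`cpmeta.sumstats`);
2. **estimates the between-panel null correlation matrix** from
   approximately independent null SNPs — greedy LD pruning at r² < 0.2 and
   a |Z| ≤ 1.96 filter, with an optional analytic correction for the
   truncation bias of that filter (`cpmeta.nullcorr`);
3. computes two **correlation-aware combined statistics** per SNP
   (`cpmeta.combine`):
   - the homogeneous-effect quadratic `[e'(RW)⁻¹T]² / [e'(WRW)⁻¹e]`
     (χ²₁ under the null) with sample-size weights, and
   - its heterogeneity-robust extension — the maximum over thresholds τ of
     the same form restricted to components with |T| > τ and sign-aligned
     weights — whose null distribution is simulated (MVN Monte Carlo with a
     fitted beta tail for extreme p-values);
4. runs the **genome-wide scan** with a conventional sample-size-weighted
   Z baseline, genomic-control λ, Q-Q/Manhattan/forest data tables, greedy
   locus clumping (lead ± 500 kb), novel-locus calls against the baseline
   and method cross-tabulation (`cpmeta.scan`);
5. **simulates** multi-cohort multi-trait Z-score panels with planted
   homogeneous / heterogeneous / sex-specific effects and known overlap
   correlation, plus block-correlated genotype fixtures (`cpmeta.simulate`).

## CLI

`cpmeta` exposes subcommands for each stage and a one-shot driver:

```sh
# synthetic panels with known truth
cpmeta simulate --config sim.yaml --out simdir/

# stage by stage
cpmeta ingest        --config run.yaml --out zpanel.tsv
cpmeta estimate-corr --zpanel zpanel.tsv --out corr.tsv
cpmeta scan          --zpanel zpanel.tsv --corr corr.tsv --seed 1 --out results.tsv
cpmeta loci          --results results.tsv --p-col p_hom --out loci.tsv
cpmeta compare       --results results.tsv --method s_het --out crosstab.tsv
cpmeta lambda        --results results.tsv --p-col p_hom

# or everything from one YAML config (simulate | ingest → … → report)
cpmeta run --config run.yaml
```

A minimal `run.yaml` for a synthetic null run:

```yaml
output_dir: myrun
seed: 1
compute_het: true
het_null_draws: 100000
simulate:
  J: 2
  K: 1
  M: 100000
  n: [60586, 73137]
  R_true: [[1.0, 0.096], [0.096, 1.0]]
  trait_ids: [bmi]
```

For real data, replace `simulate:` with a `panels:` list
(`cohort_id`, `trait_id`, `n_max`, `path`, optional `dialect:` mapping or
the literal string `giant` for the historical consortium column names).
Every run writes a `manifest.json` with the config hash, seed and artifact
paths; re-running an identical config reproduces identical outputs.

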