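# grslife

Gene-environment interaction analysis of body-fat-mass (BFM) change, built
as a tested, reusable pipeline:

1. **synthetic** — cohort generator: bi-allelic autosomal SNPs in
   Hardy-Weinberg equilibrium with configurable MAF and missingness; daily
   diet/activity diaries over a baseline + observation period with
   group-specific lifestyle shifts (low-carb, low-fat, moderate/intense
   exercise); ΔBFM generated by running the two per-SNP interaction models
   forward with planted coefficients plus Gaussian noise, and a truth
   channel for parameter-recovery tests.
2. **qc** — VCF v4.2 / PLINK `.traw` readers with minor-allele dosage
   orientation, a conditional exact Hardy-Weinberg test, and SNP filters
   (non-autosomal, indel, call rate < 0.99, MAF < 0.01, HWE p < 1e-5)
   applied in a fixed single-fate order.
3. **lifelog** — per-participant lifestyle deltas (ΔC, ΔF g/day; ΔE
   kcal/day) between baseline and observation windows with coverage
   flags, within-group median-split active/inactive classification, and
   per-person-per-week (PPPW) compliance series.
4. **interaction** — per-SNP OLS interaction models
   (ΔBFM ~ gender + age + age² + SNP + ΔC + ΔF + SNP·ΔC + SNP·ΔF, and the
   exercise analogue with ΔE), plus panel selection for the three genetic
   risk scores (GRS-C/F/E; default sizes 37/19/25).
5. **scoring** — GRS as the coefficient-weighted minor-allele dosage sum,
   with mean-impute or drop-SNP missing-dosage policies.
6. **analysis** — data-driven high/low GRS cutoff search (maximal
   between-class ΔBFM difference, or maximal |t|), Welch t-tests,
   Benjamini-Hochberg FDR over the three GRS comparisons, the four-group
   (GRS × activity) one-way ANOVA, paired pre/post summary tables, and
   Welch-t / chi-squared group summaries.
7. **pipeline / cli** — orchestration with a JSON/TOML config, per-stage
   artifacts and a deterministic run manifest.

## CLI

Full run from a config file:

```sh
grslife run --config run.toml
```

Minimal `run.toml` for a simulated demo cohort:

```toml
out_dir = "demo_out"
seed = 7
simulate = true
panel_sizes = [5, 4, 3]

[cohort]
n_participants = 259
n_snps = 30
panel_sizes = [5, 4, 3]
```

Per-stage subcommands (`simulate`, `qc`, `lifelog`, `fit`, `score`,
`analyze`) mirror the pipeline stages, e.g.:

```sh
grslife simulate --seed 7 --n-snps 30 --panel-sizes 5,4,3 --out sim/
grslife qc --genotypes sim/genotypes.vcf --format vcf --out qcdir/
grslife score --genotypes qcdir/genotypes_qc.traw --panels weights/panels.json --out scores.tsv
```

Run `grslife <command> --help` for all options.

## Notes

- Dosages always count the *sample minor* allele (0/1/2); readers
  re-orient ALT-major sites, and GRS weights keep their fitted sign.
- "Maximal quantitative difference" cutoff selection is ambiguous between
  the mean difference and the test statistic; both criteria are
  implemented (`criterion = "mean_diff"` default, `"t_stat"` optional).
- The cutoff search is a selection procedure: under the global null its
  high/low t-test rejects more often than nominal. The test suite
  documents this and verifies that a fixed median split is calibrated.
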