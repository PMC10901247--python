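# mrtool

Two-sample bidirectional Mendelian randomization from GWAS summary
statistics, with a built-in synthetic-data generator so every pipeline stage
is testable offline.

The pipeline mirrors the standard summary-level MR workflow:

1. **Instrument selection** (`mrtool.iv_selection`) — significance threshold
   (default p < 5e-6), MAF ≥ 0.01, greedy LD clumping (r² < 0.001 within
   10,000 kb), and weak-instrument exclusion (F = (beta/se)² ≥ 10), with a
   complete per-SNP audit trail.
2. **Harmonization** (`mrtool.harmonize`) — aligns outcome effects to the
   exposure's effect allele, resolving allele swaps and strand complements;
   palindromic A/T and C/G SNPs are dropped by default (or frequency-aligned
   with `--palindromes infer`).
3. **Estimation** (`mrtool.estimators`) — Wald ratio (single SNP),
   inverse-variance weighted (fixed or multiplicative-random-effects),
   MR-Egger with the intercept pleiotropy test, and the weighted median with
   a seeded parametric-bootstrap SE.
4. **Sensitivity** (`mrtool.sensitivity`) — Cochran's Q (heterogeneous when
   Q > k−1 or p < 0.05), MR-PRESSO global and outlier tests with iterative
   removal, leave-one-out, the Steiger directionality test (Fisher-z
   comparison of summed variance explained), and per-SNP F-statistics.
5. **Orchestration** (`mrtool.pipeline`) — per-pair runs and bidirectional
   screens over many exposure taxa and primary/verification outcome
   datasets, with a deterministic summary table (unadjusted headline
   p-values plus Bonferroni/BH columns for reference).
6. **Simulation** (`mrtool.simulate`) — summary statistics with known causal
   effect, horizontal pleiotropy (optionally violating InSIDE), LD blocks,
   palindromic alleles, and analytic standardized-scale SEs
   (1/sqrt(2·n·maf·(1−maf))).

All inputs and outputs are tab-separated text; column names are remappable
so IEU-style and GWAS-SSF-style exports both load.

## CLI

```sh
mrtool simulate --preset clean --seed 17 --out sim/
mrtool select --exposure sim/exposure.tsv --ld sim/ld.tsv \
    --p-threshold 5e-6 --maf 0.01 --clump-r2 0.001 --clump-kb 10000 \
    --f-min 10 --out instruments.tsv
mrtool harmonize --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
    --instruments instruments.tsv --palindromes drop --out harmonized.tsv
mrtool run --harmonized harmonized.tsv --n-boot 1000 --seed 17 --out estimates.tsv
mrtool sensitivity --harmonized harmonized.tsv --n-sim 1000 --seed 17 --out sens.json
mrtool bidir --config study.yaml
```

`study.yaml` for `bidir` lists `exposures` (TSV paths), `outcome`, `ld`,
`outdir`, `seed` and optional threshold overrides; see
`tests/test_cli.py::TestBidirCommand` for a worked example.

Identical inputs and seeds always produce byte-identical outputs.

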