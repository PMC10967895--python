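# protarget-mr

A proteome-wide Mendelian-randomization (MR) pipeline for drug-target
discovery from summary statistics, covering the full
discovery → validation → prioritisation flow:

- **`sumstats`** — summary-statistics data model and TSV/LD-matrix I/O,
  allele harmonization (including strand flips and unconditional removal of
  palindromic variants), and the cis-instrument filter chain: genome-wide
  significance (p < 5×10⁻⁸), MHC exclusion (chr6:29–33 Mb), cis window
  (±1000 kb around the gene body), MAF, instrument strength (F = (β/se)² > 10)
  and greedy LD clumping (r² < 0.001), with a per-variant selection log.
- **`mr_core`** — Wald ratio, fixed/multiplicative-random-effects IVW,
  Cochran's Q, MR-Egger intercept, Steiger directionality filtering,
  Benjamini–Hochberg FDR and the significant/suggestive/null trichotomy.
- **`colocalization`** — Wakefield approximate-Bayes-factor colocalization,
  computed entirely in log space; five-hypothesis posteriors PPH0–PPH4 with
  priors p1 = p2 = 1e-4, p12 = 1e-5 and a PPH4 ≥ 0.8 call threshold.
- **`smr_heidi`** — summary-data-based MR at the top cis-eQTL
  (T_SMR = z_g²z_e²/(z_g²+z_e²)) and the HEIDI linkage-vs-pleiotropy test
  with an Imhof quadratic-form p-value (seeded Monte-Carlo fallback).
- **`tiering`** — the four-tier target classification over five validation
  criteria, with direction consistency as a prerequisite and a separate rule
  for proteins lacking blood eQTLs. A 13-row example evidence table is
  packaged (`protarget_mr/data/paper_evidence.tsv`).
- **`phewas_scan`** — MR-PheWAS screen of one protein against an outcome
  catalog (traits with > 500 cases), with family-wise FDR correction, plus a
  local phenotype-scanning lookup for pleiotropic instruments.
- **`synthetic_data`** — seeded generator of LD-structured regional summary
  statistics (z ~ MVN(Rz_true, R)) with known causal architecture
  (shared/distinct/reverse-causal/pleiotropic/null scenarios) and an on-disk
  study-bundle writer, so the whole pipeline runs without any downloads.
- **`pipeline`** / **`cli`** — end-to-end orchestration with config,
  run manifests and TSV outputs.

## CLI

```bash
# simulate a 20-protein study bundle (5 true targets) and run everything
protarget-mr simulate --n-proteins 20 --seed 1 --out bundle/
protarget-mr run-all --bundle bundle/ --seed 1 --out results/

# individual stages
protarget-mr discover --bundle bundle/ --out results/
protarget-mr coloc --trait1 pqtl.tsv --trait2 gwas.tsv --type1 quant --type2 cc
protarget-mr smr --eqtl eqtl.tsv --gwas gwas.tsv --ld region.ld
protarget-mr tier                      # classify the packaged example table
protarget-mr tier --evidence my.tsv
protarget-mr phewas --bundle bundle/ --protein GENE001 --catalog catalog.tsv
```

Input formats (tab-delimited, documented in `sumstats.py`):

- summary statistics: `variant_id chrom pos effect_allele other_allele eaf
  beta se pvalue n [n_cases n_controls]` (foreign headers via a column map);
- LD matrix: one header line of variant ids, then a square whitespace-
  delimited correlation matrix;
- gene annotation: `gene_id chrom start end` (1-based inclusive).

## Notes

- The HEIDI pass/fail column of the packaged evidence table encodes
  published pass/fail status as representative p-values (0.5 / 0.01), since
  per-gene HEIDI p-values are not printed in the source study.
- ABF effect-size prior SDs default to 0.15 (quantitative) and 0.20
  (case-control) and are configurable.
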