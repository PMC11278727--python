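# micromr

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument selection, LD clumping, allele harmonization, Wald-ratio / IVW
estimation with Steiger directionality checking — plus a synthetic
summary-statistics generator with known ground truth so the whole pipeline
is testable offline.

## What it does

Given per-variant summary statistics for one or more quantitative exposures
and one binary outcome, `micromr`:

1. **selects instruments** per exposure — keep variants with p < 1e-8
   (strict), greedily clump with an r² threshold of 0.001 inside a 10 Mb
   window against a file-based LD reference, then drop variants with
   F = (beta/se)² below 10;
2. **harmonizes** exposure and outcome effects onto a shared effect allele —
   palindromic (A/T, C/G) variants are dropped outright, allele swaps and
   strand flips are resolved, unresolvable configurations are dropped as
   ambiguous, and variants with MAF ≤ 0.01 (exposure frequency) are excluded;
3. **estimates** the causal effect per exposure — per-instrument Wald
   ratios pooled by fixed-effect IVW (a single instrument is reported as
   `wald_ratio`), expressed as an odds ratio with 95% CI and two-sided
   Wald p, with Cochran's Q when ≥ 2 instruments and an MR Steiger
   directionality verdict from summed per-side explained variance;
4. **reports** a results table, significant/forest tables (protective
   OR < 1 vs risk OR > 1), per-variant selection/exclusion logs and a JSON
   run report with stage-by-stage instrument counts.

All thresholds are configurable (`RunConfig` / CLI flags); the defaults
above are strict-inequality keeps at p and strict-inequality drops at F
(F exactly 10 is retained; p exactly 1e-8 is excluded; MAF exactly 0.01
is excluded). Note the 1e-8 significance default is deliberately stricter
than the conventional 5e-8.

## File formats

All files are UTF-8 TSV with a header.

* **Summary statistics**: columns exactly
  `variant_id chrom pos effect_allele other_allele eaf beta se pvalue n`
  (+ `n_case n_control` for the binary outcome). Coordinates 1-based,
  alleles single ACGT bases, `beta` per effect-allele copy (per-SD units
  for exposures, log-odds for the outcome).
* **LD reference**: a directory with `positions.tsv`
  (`variant_id chrom pos`) and `ld.tsv` (`id_a id_b r`, signed r; absent
  pairs mean r = 0; the symmetric closure is applied on read).
* **Results**: `exposure_id method n_iv theta se or ci_low ci_high pvalue
  steiger_direction steiger_pvalue iv_ids`.

## CLI

```sh
# generate a synthetic panel (k exposures + shared outcome + LD reference)
micromr simulate --seed 42 --out sim/

# instrument selection only, with a per-variant disposition log
micromr select --exposure sim/exposure_taxon00.tsv --ld-dir sim/ld \
    --p-threshold 1e-8 --clump-r2 0.001 --clump-kb 10000 --min-f 10 \
    --log selection.tsv

# full run (YAML config and/or flag overrides)
micromr run --exposure sim/exposure_taxon00.tsv --outcome sim/outcome.tsv \
    --ld-dir sim/ld --out results/
```

`micromr run` writes `results.tsv`, `significant.tsv`, `forest.tsv`,
`selection_log.tsv`, `exclusion_log.tsv` and `run_report.json` into the
output directory.

## Synthetic data

`micromr.synthetic_data` draws summary statistics directly from their
sampling distribution on the standardized-genotype scale (block-diagonal
AR(1) LD, configurable causal effect, horizontal pleiotropy, confounding
loadings, and a reverse-causation mode), and also provides a slower
individual-level generator (genotypes → exposure → Bernoulli outcome →
per-variant regressions) used as a distributional oracle in the tests.
Everything is deterministic under a seed; `make_panel` writes ready-to-run
file sets plus a `truth.json`.

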