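# cardioburden

Rare-variant triage and carrier-burden analysis for a 70-gene cardiac
channelopathy/cardiomyopathy panel, built around a 290-case cohort of
annotated single-nucleotide variants.

The package provides, as importable modules and as a CLI:

- **`cardioburden.panel`** — the 70-gene panel model (23 channelopathy,
  47 cardiomyopathy genes) with per-gene disease-association codes and a
  category override map.
- **`cardioburden.io`** — readers/writers for the tab-separated case-variant
  dialect, a minimal annotated VCF route (via cyvcf2), and reference-population
  frequency tables.
- **`cardioburden.triage`** — the rule engine: >1% population-frequency
  exclusion, synonymous/intronic filtering (with splice-prediction rescue),
  putative-pathogenic / VUS / likely-benign labelling, and a simplified
  two-tier (3/4) classification with a per-row published-class override.
  Every decision carries a human-readable rule trace.
- **`cardioburden.burden`** — distinct-case carrier aggregation, cohort MAFs,
  expected reference carriers under the one-carrier-per-individual assumption,
  and exact two-sided Fisher tests (point-probability rule) at cohort,
  disease-category, gene, and variant level, plus chi-square/exact
  demographic comparisons.
- **`cardioburden.permutation`** — seeded Monte Carlo comparison of
  pathogenic-variant proportions between two variant cohorts
  (fixed-size draws without replacement by default).
- **`cardioburden.simulate`** — synthetic cohort generation with known
  carrier truth (every truth-pathogenic variant is guaranteed to triage
  pathogenic; decoys are guaranteed to be filtered), end-to-end recovery /
  type-I-error calibration, and the packaged 39-row study dataset
  (`study_fixture()`).

## CLI

```bash
# triage a variant table against the default panel
cardioburden triage --variants variants.tsv --out triaged.tsv

# carrier/gene/variant burden tests against a reference frequency table
cardioburden burden --triage triaged.tsv --cohort-size 290 \
    --ref ExAC_NFE=exac_nfe.tsv:33370 --ref-carriers SweGen=51 --out burden.tsv

# Monte Carlo permutation comparison of two variant cohorts
cardioburden permute --cohort-a a.tsv --cohort-b b.tsv \
    --iterations 10000 --sample-size 50 --seed 1 --out permute.json

# simulate a synthetic cohort with known truth
cardioburden simulate --seed 1 --out-dir sim/

# full pipeline from a YAML config (see tests/test_cli.py for the schema)
cardioburden run-all --config pipeline.yaml --out-dir results/
```

`run-all` writes `triage.tsv`, `carrier_summary.json`, `burden.tsv` and a
human-readable `summary.txt`; outputs are byte-identical across reruns of the
same config. Logs go to stderr only.

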