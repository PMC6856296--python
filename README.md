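# epicohort

Cohort-characterization toolkit for targeted gene-panel epilepsy studies.
It packages, as tested reusable code, the statistical machinery of a
pediatric epilepsy panel study:

- **`epicohort.cohort_table`** — variant-ledger data model with two TSV
  dialects (a canonical machine format and a "printed" dialect mirroring
  published cohort tables with continuation rows and section headers),
  packaged transcriptions of the study's two variant tables
  (`load_fixture("table1A"/"table1B")`, with a sidecar normalization log in
  `src/epicohort/data/transcription_notes.txt`), and VCF ingest.
- **`epicohort.constraint`** — per-gene mutation-tolerance z-scores:
  studentized residuals (internal or leave-one-out) of the OLS regression of
  missense counts on missense + synonymous counts across genes.
- **`epicohort.scores`** — case-vs-control comparison of GERP/CONDEL
  deleteriousness scores (type-7 five-number summaries, exact/asymptotic
  Wilcoxon rank-sum, discordance flags such as high-GERP/low-CONDEL).
- **`epicohort.cooccurrence`** — Poisson model for rare missense
  co-occurrence: P(two hits in one gene) = 1 − e^−λ(1+λ) and
  P(one hit in each of k genes) = Π(1 − e^−λᵢ), with two λ estimators
  (mean count, carrier frequency), a Monte-Carlo checker, and panel IO.
- **`epicohort.classify_summarize`** — MAF prioritization (< 0.01 across
  databases), the explicit segregation/frequency tier rules (R1–R5), cohort
  summaries (diagnostic yield, gene-mode split, de novo fraction, CNV
  involvement), and a classification audit with an exceptions report.
- **`epicohort.synthetic_data`** — seeded generators for count panels,
  population panels, cohort ledgers, and score samples; pure functions of
  (config, seed) with per-field substreams.

## CLI

```sh
epicohort summarize --table1a fixture:table1A --table1b fixture:table1B \
    --n-cohort 246 --json summary.json
epicohort tier --ledger fixture:table1A
epicohort audit --out exceptions.tsv
epicohort zscore --counts counts.tsv --out zscores.tsv
epicohort cooccur --lambda 0.02 --lambda 0.02 --monte-carlo 1000000
epicohort simulate cohort --n-patients 500 --seed 7 --out sim/
```

`fixture:table1A` / `fixture:table1B` refer to the packaged table
transcriptions; file arguments are canonical-dialect TSVs.

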