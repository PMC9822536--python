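# bpcpipe

A data-processing pipeline for GENIE-BPC-style clinico-genomic data
releases: multi-institution oncology real-world data in which curated
phenomic tables (patient characteristics, cancer diagnoses, drug regimens,
pathology/imaging/tumor-marker/med-onc reports, cancer panel tests) are
linked to targeted-panel sequencing results (MAF mutations, fusions, a
gene-by-sample copy-number matrix) through genomic sample IDs.

These releases are relationally complex: a patient can have several cancer
diagnoses, each diagnosis several drug regimens and several
next-generation-sequencing (NGS) reports, and only *index* cancers — the
diagnoses with associated sequencing — anchor the clinical–genomic
linkage. `bpcpipe` turns a release directory into analysis-ready tables
for biostatisticians and outcomes researchers:

- **Load & validate** — typed readers for every table, plus a referential-
  integrity validator that reports rule-level violations (orphan panel
  tests, duplicate sample IDs, regimens pointing at missing diagnoses, …)
  as data rather than exceptions.
- **Cohort construction** — subset index diagnoses by institution, stage,
  histology and drug-regimen criteria. Regimen queries are drug *sets*
  matched exactly or by containment, optionally pinned to a line of
  therapy (`order_within_cancer`: regimens of one diagnosis sorted by
  start day and numbered densely from 1). A record missing a value in a
  filtered field is excluded — the pipeline never imputes.
- **Unique NGS report selection** — one report per patient via a fixed
  cascade: preferred OncoTree code, then sample type (primary vs
  metastatic), then earliest/latest report day; remaining ties go to the
  panel with the largest number of genes, then the smallest sample ID.
  A patient with a single report always keeps it.
- **Summary tables** — "n (%)" cohort characteristic tables with
  row-conserving denominators (diagnoses, regimens or panel tests as
  appropriate) and explicit "Unknown" rows for missing data.
- **Treatment trajectories** — ordered regimen sequences aggregated into a
  prefix-count tree (ring *k* = *k*-th regimen) with a lossless
  sequence export for sunburst renderers.
- **Synthetic releases** — a seeded generator that emulates the full
  relational structure with configurable missingness, so every stage is
  testable without access-controlled data.

Real releases are distributed through the Synapse platform; obtaining and
downloading them (credentials, Terms of Use) is a manual prerequisite —
the loader takes a local directory. A bundled, editable registry file
tracks which cohort/version releases exist (`bpc versions`).

## Worked example

```python
import bpcpipe as b

release = b.synthesize_release(b.SyntheticParams(n_patients=300, seed=1))

cohort = b.create_analytic_cohort(release, b.CohortFilter(
    stage_dx={"Stage IV"},
    histology={"Adenocarcinoma"},
    regimen_queries=[
        "Carboplatin, Pemetrexed Disodium",
        "Cisplatin, Pemetrexed Disodium",
        "Bevacizumab, Carboplatin, Pemetrexed Disodium",
        "Bevacizumab, Cisplatin, Pemetrexed Disodium",
    ],
    regimen_type="exact",
    regimen_order=1,                      # first-line only
    regimen_order_type="within-cancer",
))
print(cohort.n_patients)                  # 40

tabs = b.cohort_summary_tables(cohort)
print(tabs.drugs[tabs.drugs.variable == "regimen_drugs"]
          [["level", "formatted"]].to_string(index=False))
```

```
                                        level formatted
Bevacizumab, Carboplatin, Pemetrexed Disodium    9 (22)
  Bevacizumab, Cisplatin, Pemetrexed Disodium   16 (40)
             Carboplatin, Pemetrexed Disodium    9 (22)
               Cisplatin, Pemetrexed Disodium    6 (15)
```

Of 300 synthetic patients, 40 had a Stage IV adenocarcinoma index
diagnosis whose *first* regimen was exactly one of the four queried
platinum-doublet regimens; the table shows each regimen's share of the 40
qualifying regimens in "n (%)" form (one decimal below 10%, whole numbers
above).

```python
unique = b.select_unique_ngs(
    cohort.cohort_ngs, release.tables["panels"],
    b.NgsSelectionSpec(oncotree_code="LUAD", sample_type="Metastasis"))
print(len(unique))                        # 36  (one row per sequenced patient)

tree = b.build_trajectories(release, cohort, max_n_regimens=4)
print(tree.n_contributing, tree.ring_total(2))   # 40 20
```

The trajectory tree says all 40 diagnoses contributed a first regimen and
20 went on to a second; `b.export_sunburst_sequences(tree)` flattens it to
`sequence,count` rows for any sunburst plotting library.

The same workflow is available from the shell:

```sh
bpc simulate --out release/ --n-patients 300 --seed 1
bpc validate release/
bpc cohort release/ --stage "Stage IV" --histology Adenocarcinoma \
    --regimen "Carboplatin, Pemetrexed Disodium" \
    --regimen-order 1 --out cohort/ --summary
bpc ngs-select release/ --cohort cohort/ --oncotree LUAD \
    --sample-type Metastasis --out unique_ngs.csv
bpc trajectory release/ --cohort cohort/ --max-regimens 4 --out sequences.csv
```

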