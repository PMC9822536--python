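# Methods

## The data model

A release is a set of relational tables for one (cohort, version)
snapshot. The clinical side follows the one-record-per-unit convention of
curated phenomic data: one row per patient (`pt_char`), per cancer
diagnosis (`ca_dx_index` / `ca_dx_non_index`), per drug regimen and its
diagnosis (`ca_drugs`), per pathology / imaging / tumor-marker / med-onc
report, per radiation course (optional table), and per cancer panel test
(`cpt`). The genomic side is keyed by the panel test's sample ID: MAF-style
mutations (tab-separated, `Hugo_Symbol` / `Tumor_Sample_Barcode`), fusion
records, and a wide copy-number matrix (one row per gene, one column per
sample, discrete calls in {−2…2}). A long `panels` table maps each
sequencing assay ID to its gene list.

Index cancers are the diagnoses with associated sequencing; panel tests
must link to an index diagnosis, and every patient carries at least one
(inclusion in these registries requires sequencing). The non-index table
is loaded and validated but never consulted by cohort logic.

All temporal fields are de-identified integer day offsets; calendar dates
are never constructed. Missingness is an empty field or `NA` on disk and a
nullable value in memory. The pipeline never imputes or otherwise
manipulates missing data: the only policy anywhere is *exclusion* when a
filter consults a missing field, and explicit "Unknown" rows in summaries.

File dialects are pinned per table in a layout config (CSV with a header
row for clinical tables, tab-separated MAF for mutations); other dialects
are configuration, not code. Writing is byte-stable — fixed column order,
rows sorted on each table's key columns — so releases diff cleanly and
write→load→write is the identity.

A local YAML registry replaces any live version query: it records cohort,
version, release date and an integer sequence per release, and
`list_versions(most_recent=True)` keeps the highest sequence per
(cohort, access class). Access class (public vs consortium) is derived
from the version suffix unless stated; treating it as part of the grouping
is our choice — a cohort published both ways keeps one row of each, which
matches how such listings are published.

## Cohort construction

Filters start from index diagnoses and compose conjunctively:

1. Label filters (institution, stage, histology, diagnosis ordinal) match
   case-insensitively on the exact label. A missing value in a filtered
   field fails that filter; fields not filtered on are never consulted.
2. Regimen criteria. Drug strings are canonicalized — split on commas,
   trimmed, case-folded for comparison, with a title-case display form —
   and regimens are matched as sets: `exact` is set equality against at
   least one query, `containing` is superset. No synonym dictionary is
   applied: the source vocabularies are already controlled, and silent
   synonym mapping would be a form of data manipulation.
3. Line of therapy. Within a diagnosis, regimens sort by (start day,
   regimen number), missing start days last, and are numbered densely from
   1 (`order_within_cancer`). `regimen_order` keeps diagnoses whose
   *matching* regimen sits at that position. With `within-cancer` the
   position is counted among all of the diagnosis's regimens; with
   `within-regimen` it is the rank among only the matching regimens. The
   within-regimen semantics is our design choice for a case the primary
   sources leave undemonstrated, and is stated here prominently for that
   reason.

`cohort_ca_drugs` contains exactly the qualifying regimens (all regimens
of retained diagnoses when no regimen criterion was given); `cohort_ngs`
contains every panel test joining a retained diagnosis; `cohort_pt_char`
deduplicates patients, since a patient can qualify through more than one
diagnosis. Order constraints are always evaluated against the full
release's regimens, so filtering can never renumber lines of therapy.

## Unique NGS report selection

The cascade priority is fixed: OncoTree code, then sample type, then time
preference — the order in which a caller supplies the preferences never
matters. A patient with exactly one sample keeps it regardless of the
criteria. For multi-sample patients each criterion is a *soft* filter:
it applies only if at least one remaining sample satisfies it, otherwise
it is skipped for that patient. This extends the single-sample guarantee
("every patient gets a report") uniformly to the unmatched multi-sample
case; a `strict=True` mode turns the criteria into hard filters that drop
non-matching patients instead. Remaining ties go to the panel with the
largest gene count (an unknown assay counts 0, with a warning), then to
the lexicographically smallest sample ID — the final deterministic
tie-break is ours, added because reproducible pipelines need one. Missing
report days never win on time: the time criterion only compares known
days, in either direction.

## Summary tables

`format_count_pct` renders `n (pct)` with one decimal below 10% and whole
numbers at or above, using round-half-to-even. The rule was chosen as the
simplest policy consistent with the published style of such tables and is
configurable via the `decimal_below` threshold. Denominators are rows of
the table being summarized — diagnoses, regimens or panel tests — not
patients; the records-per-patient overview uses the cohort's patient count
and reports patients absent from a table at level "0". Missing values form
an explicit "Unknown" level, listed last.

## Trajectories

Sequences are built per (patient, diagnosis): all regimens of the
diagnosis from the *full release* (not only cohort-qualifying ones),
ordered by `order_within_cancer`, truncated to `max_n_regimens`, labeled
canonically. The tree stores prefix counts, so the count of a node is the
number of sequences passing through it and ring totals are non-increasing
with depth. Diagnoses with zero regimens are excluded from the tree and
reported in a side count (`n_excluded`). The export lists complete
sequences with terminal counts (node count minus children), separator
characters inside labels escaped; it reconstructs the tree exactly.
Rendering (interactive HTML, hover behavior, colors) is left to external
sunburst libraries by design — the tested contract is the tree and its
export.

## Synthetic releases

The generator is first-class, tested code. It emulates a lung-cancer-like
release: three contributing institutions at weights 0.38/0.49/0.13;
stage distribution 15/15/20/50% (I–IV); histology 60% adenocarcinoma,
25% squamous, 15% other, with 5% missing histology by default; 0–4
regimens per diagnosis, drawn 60% of the time from common templates
(platinum doublets ± bevacizumab, single-agent immunotherapy or taxane)
and otherwise as random 1–3-drug combinations from a 10-drug pool; 1–4
panel tests per patient (80/15/4/1%), assayed on institution-specific
panels with gene counts in the 215–468 range; 0–5 mutations per sample
drawn from the sample's own panel genes; sparse fusions; a 40-gene CNA
matrix with mostly neutral calls and ~1% missing entries. These defaults
were set once to look like a plausible release of this kind and are not
tuned per experiment.

A single root seed feeds named substreams (one per table, via a CRC of the
table name), so adding a table never perturbs the others and releases are
byte-reproducible from their parameters. Every generated release satisfies
the full validator by construction: referential integrity, at least one
index diagnosis and one panel test per patient, regimen start days
increasing with regimen number.

`inject_violation` is the validator's fixture mutator: each named rule has
a mutation engineered to trip exactly that rule and no other, so validator
tests check both sensitivity and specificity.

What the generator does **not** emulate: survival and outcome processes,
genomic hotspot structure, correlated treatment choice, inter-table
timing beyond simple offsets, or institution-specific curation quirks.
Passing tests therefore demonstrate that the *relational logic* of the
pipeline is correct on data of this shape, not that any clinical result
derived from real releases is valid.

## Numerical and degenerate-input choices

- Ties everywhere break on stable sorts over declared keys, never on row
  order; shuffling input rows never changes any result.
- Empty inputs: an empty filter returns the identity cohort; an empty
  trajectory tree exports zero rows; summarizing an empty cohort is an
  error (there is no denominator).
- `Int64` (nullable) carries every day offset and ordinal, preserving
  missingness through I/O round-trips.
- Problem sizes in the test suite and the acceptance script (releases of
  8–300 patients, 200 randomized release×filter trials, 500 randomized
  multi-sample patients, 50 validator mutations, a 5 000-patient
  calibration check) were chosen to exercise every code path with
  comfortable statistical power while keeping the default suite fast.

## Known limitations

- Drug-class-based selection (immunotherapy / targeted / chemotherapy) and
  metastatic-site criteria are out of scope.
- No consolidation of alteration status across multiple NGS reports; the
  per-sample genomic linkage is exposed and the analyst chooses a policy.
- Sample types beyond the requested label (e.g. local recurrence) simply
  count as non-matching in the cascade; observed vocabularies are surfaced
  in warnings.
- Network retrieval of real releases, credentials and Terms-of-Use
  acceptance are manual prerequisites outside the package.
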