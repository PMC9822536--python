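"""Cohort characteristic tables in "n (%)" format.

Four tables describe an analytic cohort: an overall records-per-patient
summary (how many diagnoses / regimens / panel tests each patient
contributes), and categorical breakdowns of the diagnosis, regimen and NGS
tables.  Denominators differ by table: diagnoses for the diagnosis table,
regimens for the regimen table, panel tests for the NGS table.

Percent rendering policy: one decimal below 10 percent, whole numbers at or
above, round-half-to-even.  Missing values appear as an explicit "Unknown"
level — surfacing missingness beats hiding it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import AnalyticCohort

__all__ = [
    "format_count_pct",
    "summarize_categorical",
    "records_per_patient",
    "cohort_summary_tables",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = ["variable", "level", "n", "pct", "formatted"]
UNKNOWN_LEVEL = "Unknown"


def format_count_pct(n: int, denom: int, decimal_below: float = 10.0) -> str:
    """Render a count with its percentage, ``"n (pct)"``.

    Percentages below ``decimal_below`` keep one decimal place; larger ones
    round to whole numbers.  Rounding is round-half-to-even.
    """
    if denom <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= n <= denom:
        raise ValueError(f"count {n} outside [0, {denom}]")
    pct = 100.0 * n / denom
    if pct < decimal_below:
        return f"{n} ({round(pct, 1):.1f})"
    return f"{n} ({round(pct):d})"


def _rows(variable: str, tally: dict, denom: int) -> list[dict]:
    return [
        {
            "variable": variable,
            "level": level,
            "n": int(cnt),
            "pct": 100.0 * cnt / denom,
            "formatted": format_count_pct(int(cnt), denom),
        }
        for level, cnt in tally.items()
    ]


def summarize_categorical(
    table: pd.DataFrame, variable: str, denom: int | None = None
) -> pd.DataFrame:
    """One row per observed level of ``variable``, ordered lexicographically.

    Missing values are reported as an explicit ``"Unknown"`` row (last),
    never silently dropped.  ``denom`` defaults to the row count.
    """
    if variable not in table.columns:
        raise KeyError(f"variable {variable!r} not in table")
    denom = len(table) if denom is None else denom
    col = table[variable]
    tally = dict(sorted(col.dropna().astype(str).value_counts().items()))
    n_missing = int(col.isna().sum())
    if n_missing:
        tally[UNKNOWN_LEVEL] = n_missing
    return pd.DataFrame(_rows(variable, tally, denom), columns=SUMMARY_COLUMNS)


def records_per_patient(
    table: pd.DataFrame,
    variable: str = "records_per_patient",
    patients: pd.Series | None = None,
) -> pd.DataFrame:
    """Distribution of per-patient record counts.

    Levels are the observed counts (``"1"``, ``"2"``, ...); the denominator
    is the number of patients.  When ``patients`` lists the full cohort,
    patients absent from the table are reported at level ``"0"``.
    """
    per_patient = table.groupby("record_id").size()
    if patients is not None:
        per_patient = per_patient.reindex(pd.Index(set(patients)), fill_value=0)
    denom = len(per_patient)
    tally = {
        str(k): v for k, v in sorted(per_patient.value_counts().items())
    }
    return pd.DataFrame(_rows(variable, tally, denom), columns=SUMMARY_COLUMNS)


@dataclass
class CohortSummaries:
    """The four summary tables of an analytic cohort."""

    overall: pd.DataFrame
    dx: pd.DataFrame
    drugs: pd.DataFrame
    ngs: pd.DataFrame

    def items(self):
        return {
            "overall": self.overall,
            "dx": self.dx,
            "drugs": self.drugs,
            "ngs": self.ngs,
        }.items()


def _with_institution(df: pd.DataFrame, pt: pd.DataFrame) -> pd.DataFrame:
    if "institution" in df.columns:
        return df
    return df.merge(pt[["record_id", "institution"]], on="record_id", how="left")


def cohort_summary_tables(cohort: AnalyticCohort) -> CohortSummaries:
    """Build the overall / diagnosis / regimen / NGS summary tables.

    The overall table shows records-per-patient distributions over the
    cohort's patients.  The diagnosis table summarizes cohort, institution,
    stage and histology over *diagnoses*; the regimen table summarizes
    cohort, institution and the canonical regimen label over *regimens*;
    the NGS table summarizes cohort, institution, OncoTree code and
    sequencing assay over *panel tests*.
    """
    if cohort.cohort_ca_dx.empty:
        raise ValueError("cannot summarize an empty cohort")
    pt = cohort.cohort_pt_char
    patients = pt["record_id"]

    overall = pd.concat(
        [
            records_per_patient(cohort.cohort_ca_dx, "diagnoses_per_patient", patients),
            records_per_patient(cohort.cohort_ca_drugs, "regimens_per_patient", patients),
            records_per_patient(cohort.cohort_ngs, "cpts_per_patient", patients),
        ],
        ignore_index=True,
    )

    dx = _with_institution(cohort.cohort_ca_dx, pt)
    dx = dx.assign(cohort=cohort.cohort_name)
    tbl_dx = pd.concat(
        [
            summarize_categorical(dx, v)
            for v in ("cohort", "institution", "stage_dx", "histology")
        ],
        ignore_index=True,
    )

    drugs = _with_institution(cohort.cohort_ca_drugs, pt).assign(
        cohort=cohort.cohort_name
    )
    tbl_drugs = pd.concat(
        [summarize_categorical(drugs, v) for v in ("cohort", "institution", "regimen_drugs")],
        ignore_index=True,
    )

    ngs = _with_institution(cohort.cohort_ngs, pt).assign(cohort=cohort.cohort_name)
    tbl_ngs = pd.concat(
        [
            summarize_categorical(ngs, v)
            for v in ("cohort", "institution", "oncotree_code", "seq_assay_id")
        ],
        ignore_index=True,
    )
    return CohortSummaries(overall=overall, dx=tbl_dx, drugs=tbl_drugs, ngs=tbl_ngs)
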