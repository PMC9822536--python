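"""Select one next-generation-sequencing report per patient.

Patients may carry several cancer panel tests (repeat testing over time, or
primary versus metastatic site).  To keep one-record-per-patient structure
for clinico-genomic merges, a single report is chosen per patient through a
prioritized cascade: OncoTree code first, sample type second, report time
last, with the largest gene panel as the default tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .release import panel_gene_counts

__all__ = ["NgsSelectionSpec", "select_unique_ngs"]


@dataclass(frozen=True)
class NgsSelectionSpec:
    """User preferences for the report-selection cascade.

    All fields are optional.  The cascade priority is fixed — OncoTree code,
    then sample type, then time — regardless of the order in which a caller
    supplies the fields.
    """

    oncotree_code: Optional[str] = None
    sample_type: Optional[str] = None
    time_preference: Optional[str] = None  # "earliest" | "latest"

    def __post_init__(self) -> None:
        if self.time_preference not in (None, "earliest", "latest"):
            raise ValueError("time_preference must be 'earliest' or 'latest'")


def _soft_filter(group: pd.DataFrame, mask: pd.Series) -> pd.DataFrame:
    """Apply a criterion only if at least one sample satisfies it."""
    return group[mask] if mask.any() else group


def _warn_unobserved(spec: NgsSelectionSpec, cohort_ngs: pd.DataFrame) -> None:
    for field_, column in (
        ("oncotree_code", "oncotree_code"),
        ("sample_type", "sample_type"),
    ):
        wanted = getattr(spec, field_)
        if wanted is None:
            continue
        observed = set(cohort_ngs[column].dropna().astype(str).str.casefold())
        if str(wanted).casefold() not in observed:
            warnings.warn(
                f"{field_} {wanted!r} not observed in cohort; observed: {sorted(observed)}",
                stacklevel=3,
            )


def select_unique_ngs(
    cohort_ngs: pd.DataFrame,
    panels: pd.DataFrame,
    spec: NgsSelectionSpec | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Reduce an NGS table to exactly one report per patient.

    Per patient:

    1. A patient with exactly one sample keeps it, whether or not it meets
       the requested criteria.
    2. Otherwise the criteria apply in fixed order — OncoTree code, sample
       type, then time preference — each as a *soft* filter: a criterion
       that no remaining sample satisfies is skipped for that patient.  The
       time criterion keeps the samples at the minimum ("earliest") or
       maximum ("latest") known report day; missing report days never win.
    3. Ties are broken by the panel with the largest number of genes
       (unknown assays count 0 genes, with a warning), then by the
       lexicographically smallest sample ID so results are reproducible.

    With ``strict=True`` the criteria are hard filters instead: patients
    with no satisfying sample (including single-sample patients) are
    dropped rather than falling through the cascade.
    """
    spec = spec or NgsSelectionSpec()
    if cohort_ngs.empty:
        return cohort_ngs.copy()
    _warn_unobserved(spec, cohort_ngs)

    counts = panel_gene_counts(panels)
    unknown = set(cohort_ngs["seq_assay_id"].dropna()) - set(counts)
    if unknown:
        warnings.warn(
            f"seq_assay_id(s) {sorted(unknown)} not in panel definitions; "
            "treating gene count as 0",
            stacklevel=2,
        )

    keep_filter = _hard_filter if strict else _soft_filter
    chosen: list[int] = []
    for _, group in cohort_ngs.groupby("record_id", sort=True):
        if len(group) == 1 and not strict:
            chosen.append(group.index[0])
            continue
        g = group
        if spec.oncotree_code is not None:
            mask = (
                g["oncotree_code"].astype("string").str.casefold()
                == str(spec.oncotree_code).casefold()
            ).fillna(False)
            g = keep_filter(g, mask)
        if len(g) and spec.sample_type is not None:
            mask = (
                g["sample_type"].astype("string").str.casefold()
                == str(spec.sample_type).casefold()
            ).fillna(False)
            g = keep_filter(g, mask)
        if len(g) > 1 and spec.time_preference is not None:
            days = g["report_day"]
            if days.notna().any():
                best = days.min() if spec.time_preference == "earliest" else days.max()
                g = g[days == best]
        if len(g) == 0:
            continue  # strict mode: nothing satisfied the criteria
        if len(g) > 1:
            sizes = g["seq_assay_id"].map(lambda a: counts.get(a, 0)).fillna(0)
            g = g[sizes == sizes.max()]
        if len(g) > 1:
            g = g.loc[[g["sample_id"].idxmin()]]
        chosen.append(g.index[0])
    return cohort_ngs.loc[chosen].reset_index(drop=True)


def _hard_filter(group: pd.DataFrame, mask: pd.Series) -> pd.DataFrame:
    return group[mask]
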