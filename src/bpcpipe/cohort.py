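"""Analytic cohort construction from a data release.

Cohorts are built from *index* cancer diagnoses (the diagnoses with
associated genomic sequencing) by filtering on institution, stage,
histology, diagnosis ordinal and drug-regimen criteria.  A record with a
missing value in any field being filtered on does not meet the criteria and
is excluded; fields not filtered on are never consulted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

__all__ = [
    "CohortFilter",
    "AnalyticCohort",
    "parse_drug_set",
    "canonical_regimen_label",
    "display_drug_name",
    "regimen_matches",
    "assign_regimen_order",
    "create_analytic_cohort",
]


# --------------------------------------------------------------------------
# Drug-name canonicalization
# --------------------------------------------------------------------------


def parse_drug_set(text: str) -> frozenset[str]:
    """Parse a comma-separated drug string into a set of canonical names.

    Names are trimmed, whitespace-collapsed and case-folded so that
    ``"pemetrexed disodium,CARBOPLATIN"`` and
    ``"Carboplatin, Pemetrexed Disodium"`` parse to the same set.  Empty
    input gives the empty set.
    """
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return frozenset()
    parts = [" ".join(p.split()) for p in str(text).split(",")]
    return frozenset(p.casefold() for p in parts if p)


def display_drug_name(drug: str) -> str:
    """One display form for a canonical drug name (title case)."""
    return str(drug).strip().title()


def canonical_regimen_label(drugs: Iterable[str]) -> str:
    """Alphabetized, comma-joined display label of a drug set.

    ``{"carboplatin", "bevacizumab"}`` -> ``"Bevacizumab, Carboplatin"``.
    The label is a fixed point: parsing it and re-labelling returns it.
    """
    names = sorted(display_drug_name(d) for d in drugs)
    if not names:
        raise ValueError("cannot label an empty drug set")
    return ", ".join(names)


def regimen_matches(
    regimen_drugs: frozenset[str] | Iterable[str],
    queries: Sequence[Iterable[str]],
    mode: str = "exact",
) -> bool:
    """Whether a regimen's drug set satisfies at least one query set.

    ``exact`` requires set equality with a query; ``containing`` requires
    the regimen to be a superset of a query.
    """
    drugs = frozenset(regimen_drugs)
    mode = mode.lower()
    if mode not in ("exact", "containing"):
        raise ValueError(f"unknown regimen_type {mode!r}")
    for q in queries:
        qs = frozenset(q)
        if mode == "exact" and drugs == qs:
            return True
        if mode == "containing" and drugs >= qs:
            return True
    return False


# --------------------------------------------------------------------------
# Regimen ordering (line of therapy)
# --------------------------------------------------------------------------


def assign_regimen_order(regimens: pd.DataFrame) -> pd.DataFrame:
    """Derive dense line-of-therapy ordinals for drug regimens.

    Within each (record_id, ca_seq) pair, regimens are sorted by
    (start_day, regimen_number) — missing start days sort last — and
    numbered densely from 1 into ``order_within_cancer``.  The same ordering
    across all of a patient's regimens gives ``order_within_patient``.
    """
    df = regimens.copy()
    if df.duplicated(["record_id", "ca_seq", "regimen_number"]).any():
        raise ValueError("duplicate (record_id, ca_seq, regimen_number) in regimens")
    df = df.sort_values(
        ["record_id", "ca_seq", "start_day", "regimen_number"],
        kind="stable",
        na_position="last",
    )
    df["order_within_cancer"] = df.groupby(["record_id", "ca_seq"]).cumcount() + 1
    pat = df.sort_values(
        ["record_id", "start_day", "regimen_number"], kind="stable", na_position="last"
    )
    df["order_within_patient"] = (
        pat.groupby("record_id").cumcount().reindex(df.index) + 1
    )
    return df.sort_index()


# --------------------------------------------------------------------------
# Filter and cohort containers
# --------------------------------------------------------------------------


@dataclass
class CohortFilter:
    """Inclusion criteria for cohort construction.

    Label matching (institution, stage, histology) is case-insensitive on
    the exact label.  ``regimen_queries`` are drug sets (or comma-separated
    strings, parsed on use); ``regimen_order`` restricts to regimens at a
    given line of therapy, counted within the cancer diagnosis
    (``within-cancer``) or among only the matching regimens
    (``within-regimen``).
    """

    institutions: Optional[set[str]] = None
    stage_dx: Optional[set[str]] = None
    histology: Optional[set[str]] = None
    index_ca_seq: Optional[set[int]] = None
    regimen_queries: Optional[list] = None
    regimen_type: Literal["exact", "containing"] = "exact"
    regimen_order: Optional[int] = None
    regimen_order_type: Literal["within-cancer", "within-regimen"] = "within-cancer"

    def query_sets(self) -> Optional[list[frozenset[str]]]:
        if self.regimen_queries is None:
            return None
        out = []
        for q in self.regimen_queries:
            qs = parse_drug_set(q) if isinstance(q, str) else frozenset(
                d.casefold() for d in q
            )
            if not qs:
                raise ValueError("regimen query sets must be non-empty")
            out.append(qs)
        return out


@dataclass
class AnalyticCohort:
    """The filtered tables returned by cohort construction."""

    cohort_name: str
    cohort_pt_char: pd.DataFrame
    cohort_ca_dx: pd.DataFrame
    cohort_ca_drugs: pd.DataFrame
    cohort_ngs: pd.DataFrame
    summaries: Optional[dict] = None

    @property
    def n_patients(self) -> int:
        return int(self.cohort_pt_char["record_id"].nunique())


def _fold(s: pd.Series) -> pd.Series:
    return s.astype("string").str.casefold()


def _key_mask(df: pd.DataFrame, keys: set[tuple]) -> pd.Series:
    """Row mask of (record_id, ca_seq) membership; safe on empty frames."""
    return pd.Series(
        [k in keys for k in zip(df["record_id"], df["ca_seq"])],
        index=df.index,
        dtype=bool,
    )


def _label_filter(
    df: pd.DataFrame, column: str, wanted: Optional[set[str]]
) -> pd.Series:
    """Case-insensitive label membership; missing values fail the filter."""
    if wanted is None:
        return pd.Series(True, index=df.index)
    wanted_f = {str(w).casefold() for w in wanted}
    observed = set(df[column].dropna().astype(str).str.casefold())
    unknown = wanted_f - observed
    if unknown:
        warnings.warn(
            f"filter on '{column}' requests unobserved level(s) {sorted(unknown)}; "
            f"observed levels: {sorted(observed)}",
            stacklevel=3,
        )
    return _fold(df[column]).isin(wanted_f).fillna(False).astype(bool)


def create_analytic_cohort(release, filt: CohortFilter | None = None) -> AnalyticCohort:
    """Subset a release to the diagnoses meeting the filter criteria.

    Starting from the index diagnoses: institution/stage/histology/ordinal
    filters are applied first (nulls in a filtered field exclude the
    record); then, if regimen criteria are given, a diagnosis is retained
    iff at least one of its regimens matches the drug queries and — when a
    regimen order is requested — sits at that line of therapy.

    ``cohort_ca_drugs`` contains exactly the qualifying regimens (all
    regimens of retained diagnoses when no regimen criterion was given);
    ``cohort_ngs`` contains every cancer panel test of a retained diagnosis;
    ``cohort_pt_char`` has one row per retained patient.
    """
    filt = filt or CohortFilter()
    pt = release.tables["pt_char"]
    dx = release.tables["ca_dx_index"].copy()
    drugs = release.tables["ca_drugs"]
    cpt = release.tables["cpt"]

    dx = dx.merge(pt[["record_id", "institution"]], on="record_id", how="left")

    keep = _label_filter(dx, "institution", filt.institutions)
    keep &= _label_filter(dx, "stage_dx", filt.stage_dx)
    keep &= _label_filter(dx, "histology", filt.histology)
    if filt.index_ca_seq is not None:
        keep &= dx["ca_seq"].isin(list(filt.index_ca_seq)).fillna(False).astype(bool)
    dx = dx.loc[keep]

    queries = filt.query_sets()
    has_regimen_criterion = queries is not None or filt.regimen_order is not None

    ordered = assign_regimen_order(drugs)
    ordered["_drugset"] = ordered["regimen_drugs"].map(parse_drug_set)
    dx_keys = set(map(tuple, dx[["record_id", "ca_seq"]].itertuples(index=False)))
    ordered = ordered.loc[_key_mask(ordered, dx_keys)]

    if has_regimen_criterion:
        if queries is not None:
            ordered["_match"] = ordered["_drugset"].map(
                lambda d: regimen_matches(d, queries, filt.regimen_type)
            )
        else:
            # an order constraint without drug queries: every regimen is
            # eligible as "matching"
            ordered["_match"] = True
        matching = ordered.loc[ordered["_match"].astype(bool)].copy()
        if filt.regimen_order is not None:
            if filt.regimen_order_type == "within-cancer":
                qualifying = matching[
                    matching["order_within_cancer"] == filt.regimen_order
                ]
            else:  # within-regimen: rank among matching regimens only
                matching = matching.sort_values(
                    ["record_id", "ca_seq", "start_day", "regimen_number"],
                    kind="stable",
                    na_position="last",
                )
                rank = matching.groupby(["record_id", "ca_seq"]).cumcount() + 1
                qualifying = matching[rank == filt.regimen_order]
        else:
            qualifying = matching
        kept_keys = set(
            map(tuple, qualifying[["record_id", "ca_seq"]].itertuples(index=False))
        )
        dx = dx.loc[_key_mask(dx, kept_keys)]
        cohort_drugs = qualifying.drop(columns=["_drugset", "_match"])
    else:
        cohort_drugs = ordered.drop(columns=["_drugset"])

    dx_keys = set(map(tuple, dx[["record_id", "ca_seq"]].itertuples(index=False)))
    cohort_ngs = cpt.loc[_key_mask(cpt, dx_keys)].copy()
    cohort_pt = pt[pt["record_id"].isin(dx["record_id"])].copy()

    return AnalyticCohort(
        cohort_name=release.key.cohort_name,
        cohort_pt_char=cohort_pt.reset_index(drop=True),
        cohort_ca_dx=dx.reset_index(drop=True),
        cohort_ca_drugs=cohort_drugs.reset_index(drop=True),
        cohort_ngs=cohort_ngs.reset_index(drop=True),
    )
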