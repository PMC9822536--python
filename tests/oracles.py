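"""Independent brute-force reference implementations used only by tests.

These apply the written selection rules literally, row by row, with no
shared code paths with the package (no pandas group-bys, no vectorized
filters), so agreement is meaningful.
"""

from __future__ import annotations

import math

import pandas as pd


def _isna(x) -> bool:
    try:
        return bool(pd.isna(x))
    except (TypeError, ValueError):
        return False


def _split_drugs(text) -> frozenset[str]:
    if _isna(text):
        return frozenset()
    return frozenset(
        " ".join(p.split()).casefold() for p in str(text).split(",") if p.strip()
    )


def _fold(x) -> str:
    return str(x).casefold()


def order_regimens(rows: list[dict]) -> list[tuple[dict, int]]:
    """(regimen row, within-cancer order) by literal sort-and-enumerate."""
    def sort_key(r):
        day = r["start_day"]
        return (math.inf if _isna(day) else int(day), int(r["regimen_number"]))

    out = []
    by_dx: dict[tuple, list[dict]] = {}
    for r in rows:
        by_dx.setdefault((r["record_id"], r["ca_seq"]), []).append(r)
    for _, group in by_dx.items():
        for i, r in enumerate(sorted(group, key=sort_key), start=1):
            out.append((r, i))
    return out


def brute_force_cohort(release, filt) -> dict:
    """Literal re-implementation of cohort construction.

    Enumerates every (diagnosis, regimen) pair and applies each written
    rule directly.  Returns the retained diagnosis keys, qualifying regimen
    keys, panel-test sample IDs and patient IDs.
    """
    pt_rows = release.tables["pt_char"].to_dict("records")
    inst_of = {r["record_id"]: r["institution"] for r in pt_rows}
    dx_rows = release.tables["ca_dx_index"].to_dict("records")
    drug_rows = release.tables["ca_drugs"].to_dict("records")
    cpt_rows = release.tables["cpt"].to_dict("records")

    def label_ok(value, wanted) -> bool:
        if wanted is None:
            return True
        if _isna(value):
            return False
        return _fold(value) in {_fold(w) for w in wanted}

    ordered = order_regimens(drug_rows)

    queries = None
    if filt.regimen_queries is not None:
        queries = []
        for q in filt.regimen_queries:
            queries.append(
                _split_drugs(q) if isinstance(q, str) else frozenset(_fold(d) for d in q)
            )
    has_regimen_criterion = queries is not None or filt.regimen_order is not None

    def matches(drugset) -> bool:
        if queries is None:
            return True
        for q in queries:
            if filt.regimen_type == "exact" and drugset == q:
                return True
            if filt.regimen_type == "containing" and drugset >= q:
                return True
        return False

    retained_dx: set[tuple] = set()
    qualifying_regimens: set[tuple] = set()
    for dx in dx_rows:
        if not label_ok(inst_of.get(dx["record_id"]), filt.institutions):
            continue
        if not label_ok(dx["stage_dx"], filt.stage_dx):
            continue
        if not label_ok(dx["histology"], filt.histology):
            continue
        if filt.index_ca_seq is not None:
            if _isna(dx["ca_seq"]) or int(dx["ca_seq"]) not in filt.index_ca_seq:
                continue
        key = (dx["record_id"], dx["ca_seq"])
        regs = [(r, o) for r, o in ordered if (r["record_id"], r["ca_seq"]) == key]
        regs.sort(key=lambda ro: ro[1])
        if not has_regimen_criterion:
            retained_dx.add(key)
            for r, _ in regs:
                qualifying_regimens.add((r["record_id"], r["ca_seq"], r["regimen_number"]))
            continue
        matching = [(r, o) for r, o in regs if matches(_split_drugs(r["regimen_drugs"]))]
        if filt.regimen_order is None:
            quals = matching
        elif filt.regimen_order_type == "within-cancer":
            quals = [(r, o) for r, o in matching if o == filt.regimen_order]
        else:  # within-regimen: rank among the matching regimens only
            quals = [
                (r, o)
                for rank, (r, o) in enumerate(matching, start=1)
                if rank == filt.regimen_order
            ]
        if quals:
            retained_dx.add(key)
            for r, _ in quals:
                qualifying_regimens.add((r["record_id"], r["ca_seq"], r["regimen_number"]))

    ngs_samples = {
        c["sample_id"]
        for c in cpt_rows
        if (c["record_id"], c["ca_seq"]) in retained_dx
    }
    patients = {rid for rid, _ in retained_dx}
    return {
        "dx": retained_dx,
        "regimens": qualifying_regimens,
        "ngs": ngs_samples,
        "patients": patients,
    }


def ngs_oracle(samples: list[dict], spec, gene_counts: dict) -> str:
    """Literal enumeration of the report-selection cascade for one patient."""
    if len(samples) == 1:
        return samples[0]["sample_id"]
    remaining = list(samples)
    if spec.oncotree_code is not None:
        hits = [
            s
            for s in remaining
            if not _isna(s["oncotree_code"])
            and _fold(s["oncotree_code"]) == _fold(spec.oncotree_code)
        ]
        if hits:
            remaining = hits
    if spec.sample_type is not None:
        hits = [
            s
            for s in remaining
            if not _isna(s["sample_type"])
            and _fold(s["sample_type"]) == _fold(spec.sample_type)
        ]
        if hits:
            remaining = hits
    if spec.time_preference is not None and len(remaining) > 1:
        days = [int(s["report_day"]) for s in remaining if not _isna(s["report_day"])]
        if days:
            best = min(days) if spec.time_preference == "earliest" else max(days)
            remaining = [
                s
                for s in remaining
                if not _isna(s["report_day"]) and int(s["report_day"]) == best
            ]
    if len(remaining) > 1:
        biggest = max(gene_counts.get(s["seq_assay_id"], 0) for s in remaining)
        remaining = [
            s for s in remaining if gene_counts.get(s["seq_assay_id"], 0) == biggest
        ]
    return min(s["sample_id"] for s in remaining)


def prefix_counts(sequences: list[tuple[str, ...]]) -> dict[tuple[str, ...], int]:
    """Naive prefix tally over label sequences."""
    counts: dict[tuple[str, ...], int] = {}
    for seq in sequences:
        for k in range(1, len(seq) + 1):
            counts[seq[:k]] = counts.get(seq[:k], 0) + 1
    return counts
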