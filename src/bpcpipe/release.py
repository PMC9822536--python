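"""Domain model, readers/writers, validation and a local version registry.

A *data release* is one frozen snapshot of a clinico-genomic cohort
(e.g. ``("NSCLC", "v2.0-public")``): a set of relational clinical tables
(patients, cancer diagnoses, drug regimens, pathology/imaging/tumor-marker/
med-onc report tables, cancer panel tests) plus the genomic files keyed by
genomic sample ID (MAF-style mutations, fusions, a wide gene-by-sample
copy-number matrix) and a gene-panel definition table.

All temporal fields are de-identified integer day offsets; calendar dates are
never constructed.  Missing values are empty fields or ``NA`` on disk and
nullable values in memory — nothing is ever imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "ReleaseKey",
    "Layout",
    "DataRelease",
    "Violation",
    "MissingTableError",
    "load_release",
    "write_release",
    "validate_release",
    "list_versions",
    "panel_gene_count",
    "RULE_IDS",
]


# --------------------------------------------------------------------------
# Table schemas
# --------------------------------------------------------------------------

#: minimal required columns per table; extra columns pass through untouched
REQUIRED_COLUMNS: dict[str, list[str]] = {
    "pt_char": ["record_id", "institution"],
    "ca_dx_index": ["record_id", "ca_seq", "stage_dx", "histology", "dx_day"],
    "ca_dx_non_index": ["record_id", "ca_seq", "stage_dx", "histology", "dx_day"],
    "ca_drugs": [
        "record_id",
        "ca_seq",
        "regimen_number",
        "regimen_drugs",
        "start_day",
        "end_day",
    ],
    "prissmm_pathology": ["record_id", "report_day"],
    "prissmm_imaging": ["record_id", "report_day"],
    "prissmm_tm": ["record_id", "report_day"],
    "prissmm_md": ["record_id", "report_day"],
    "ca_radtx": ["record_id", "ca_seq", "start_day"],
    "cpt": [
        "record_id",
        "ca_seq",
        "sample_id",
        "oncotree_code",
        "sample_type",
        "seq_assay_id",
        "report_day",
    ],
    "mutations": [
        "Hugo_Symbol",
        "Tumor_Sample_Barcode",
        "Variant_Classification",
        "HGVSp_Short",
    ],
    "fusions": ["hugo_symbol", "sample_id", "fusion"],
    "panels": ["seq_assay_id", "hugo_symbol"],
    # "cna" is a wide matrix: first column "hugo_symbol", one column per sample
}

#: pass-through columns we expect to see and do not warn about
EXPECTED_EXTRA_COLUMNS: dict[str, set[str]] = {
    "pt_char": {"vital_status"},
}

#: nullable integer columns (de-identified day offsets and ordinals)
INT_COLUMNS: dict[str, list[str]] = {
    "ca_dx_index": ["ca_seq", "dx_day"],
    "ca_dx_non_index": ["ca_seq", "dx_day"],
    "ca_drugs": ["ca_seq", "regimen_number", "start_day", "end_day"],
    "prissmm_pathology": ["report_day"],
    "prissmm_imaging": ["report_day"],
    "prissmm_tm": ["report_day"],
    "prissmm_md": ["report_day"],
    "ca_radtx": ["ca_seq", "start_day"],
    "cpt": ["ca_seq", "report_day"],
}

#: deterministic row ordering used by write_release (and by the generator)
SORT_KEYS: dict[str, list[str]] = {
    "pt_char": ["record_id"],
    "ca_dx_index": ["record_id", "ca_seq"],
    "ca_dx_non_index": ["record_id", "ca_seq"],
    "ca_drugs": ["record_id", "ca_seq", "regimen_number"],
    "prissmm_pathology": ["record_id", "report_day"],
    "prissmm_imaging": ["record_id", "report_day"],
    "prissmm_tm": ["record_id", "report_day"],
    "prissmm_md": ["record_id", "report_day"],
    "ca_radtx": ["record_id", "ca_seq", "start_day"],
    "cpt": ["record_id", "ca_seq", "sample_id"],
    "mutations": ["Tumor_Sample_Barcode", "Hugo_Symbol", "HGVSp_Short"],
    "fusions": ["sample_id", "hugo_symbol", "fusion"],
    "panels": ["seq_assay_id", "hugo_symbol"],
}

OPTIONAL_TABLES = frozenset({"ca_radtx"})

CLINICAL_TABLES = (
    "pt_char",
    "ca_dx_index",
    "ca_dx_non_index",
    "ca_drugs",
    "prissmm_pathology",
    "prissmm_imaging",
    "prissmm_tm",
    "prissmm_md",
    "ca_radtx",
    "cpt",
)
GENOMIC_TABLES = ("mutations", "fusions", "cna", "panels")
ALL_TABLES = CLINICAL_TABLES + GENOMIC_TABLES


class MissingTableError(FileNotFoundError):
    """A mandatory table file is absent from the release directory."""


@dataclass(frozen=True)
class ReleaseKey:
    """Identifies one data release: a cancer cohort plus a version string."""

    cohort_name: str
    version: str
    release_date: str = ""

    def __post_init__(self) -> None:
        if not self.cohort_name:
            raise ValueError("cohort_name must be non-empty")
        if not self.version:
            raise ValueError("version must be non-empty")


# --------------------------------------------------------------------------
# Layout: file names and dialects, pinned per table
# --------------------------------------------------------------------------

_DEFAULT_FILES = {
    "pt_char": "patient_characteristics.csv",
    "ca_dx_index": "cancer_diagnosis_index.csv",
    "ca_dx_non_index": "cancer_diagnosis_non_index.csv",
    "ca_drugs": "drug_regimens.csv",
    "prissmm_pathology": "pathology.csv",
    "prissmm_imaging": "imaging.csv",
    "prissmm_tm": "tumor_markers.csv",
    "prissmm_md": "med_onc_assessments.csv",
    "ca_radtx": "radiation.csv",
    "cpt": "cancer_panel_tests.csv",
    "mutations": "mutations_extended.txt",
    "fusions": "fusions.csv",
    "cna": "cna.csv",
    "panels": "gene_panels.csv",
}

#: per-table field separator; mutations use the tab-separated MAF dialect
_DEFAULT_SEPS = {name: ("\t" if name == "mutations" else ",") for name in _DEFAULT_FILES}


@dataclass
class Layout:
    """Maps logical table names to file names and delimiters.

    Other dialects are configuration, not code: a YAML layout file may
    override any file name or separator.
    """

    files: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_FILES))
    seps: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_SEPS))

    def __post_init__(self) -> None:
        unknown = set(self.files) - set(_DEFAULT_FILES)
        if unknown:
            raise ValueError(f"layout names unknown tables: {sorted(unknown)}")
        for name in _DEFAULT_FILES:
            self.files.setdefault(name, _DEFAULT_FILES[name])
            self.seps.setdefault(name, _DEFAULT_SEPS[name])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Layout":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(files=dict(raw.get("files", {})), seps=dict(raw.get("seps", {})))


# --------------------------------------------------------------------------
# DataRelease container
# --------------------------------------------------------------------------


@dataclass
class DataRelease:
    """All clinical and genomic tables of one (cohort, version) release.

    ``tables`` maps table name to a DataFrame; the optional radiation table
    may be ``None``.  The CNA table is wide: ``hugo_symbol`` plus one
    nullable-integer column per genomic sample.
    """

    key: ReleaseKey
    tables: dict[str, pd.DataFrame | None]

    def __getattr__(self, name: str):
        tables = self.__dict__.get("tables", {})
        if name in tables or name in ALL_TABLES:
            return tables.get(name)
        raise AttributeError(name)

    def table(self, name: str) -> pd.DataFrame | None:
        return self.tables.get(name)

    def copy(self) -> "DataRelease":
        return DataRelease(
            key=self.key,
            tables={k: (None if v is None else v.copy()) for k, v in self.tables.items()},
        )

    def equals(self, other: "DataRelease") -> bool:
        if self.key != other.key:
            return False
        if set(self.tables) != set(other.tables):
            return False
        for name, mine in self.tables.items():
            theirs = other.tables[name]
            if (mine is None) != (theirs is None):
                return False
            if mine is None:
                continue
            if not mine.reset_index(drop=True).equals(theirs.reset_index(drop=True)):
                return False
        return True


def sort_table(name: str, df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic row order for a table (stable sort on its key columns)."""
    keys = SORT_KEYS.get(name)
    if name == "cna":
        df = df.sort_values("hugo_symbol", kind="stable")
        cols = ["hugo_symbol"] + sorted(c for c in df.columns if c != "hugo_symbol")
        return df[cols].reset_index(drop=True)
    if not keys:
        return df.reset_index(drop=True)
    keys = [k for k in keys if k in df.columns]
    return df.sort_values(keys, kind="stable", na_position="last").reset_index(drop=True)


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------


def _postprocess(name: str, df: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Nullify empty/"NA" fields, cast day-offset columns, check columns."""
    df = df.replace({"": pd.NA, "NA": pd.NA})
    required = REQUIRED_COLUMNS.get(name, [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: table '{name}' missing required columns {missing}")
    expected = EXPECTED_EXTRA_COLUMNS.get(name, set())
    extra = [c for c in df.columns if c not in required and c not in expected]
    if extra and name in REQUIRED_COLUMNS:
        warnings.warn(
            f"{path}: table '{name}' has extra columns {extra}; passing through",
            stacklevel=3,
        )
    for col in INT_COLUMNS.get(name, []):
        try:
            df[col] = df[col].astype("Int64")
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = int(bad.index[0]) + 2 if len(bad) else "?"  # header is line 1
            raise ValueError(f"{path}, line {row}: malformed integer in '{col}': {exc}") from exc
    return df


def _read_table(name: str, path: Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return _postprocess(name, df, path)


def _read_cna(path: Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "hugo_symbol" not in df.columns:
        raise ValueError(f"{path}: CNA matrix must have a 'hugo_symbol' first column")
    df = df.replace({"": pd.NA, "NA": pd.NA})
    for col in df.columns:
        if col != "hugo_symbol":
            df[col] = df[col].astype("Int64")
    return df


def load_release(
    root_path: str | Path,
    key: ReleaseKey,
    layout: Layout | None = None,
) -> DataRelease:
    """Load a release from a directory of delimited text files.

    Missing mandatory files raise :class:`MissingTableError` naming the
    table; the radiation table is optional and loads as ``None`` when its
    file is absent.  Drug strings are canonicalized on read (trimmed,
    alphabetized, one display form) so regimen labels compare consistently.
    """
    root = Path(root_path)
    layout = layout or Layout()
    tables: dict[str, pd.DataFrame | None] = {}
    for name in ALL_TABLES:
        path = root / layout.files[name]
        if not path.exists():
            if name in OPTIONAL_TABLES:
                tables[name] = None
                continue
            raise MissingTableError(
                f"mandatory table '{name}' not found: expected file {path}"
            )
        if name == "cna":
            tables[name] = _read_cna(path, layout.seps[name])
        else:
            tables[name] = _read_table(name, path, layout.seps[name])

    drugs = tables["ca_drugs"]
    if drugs is not None and len(drugs):
        from .cohort import canonical_regimen_label, parse_drug_set

        def _canon(s):
            if pd.isna(s):
                return s
            ds = parse_drug_set(s)
            return canonical_regimen_label(ds) if ds else pd.NA

        drugs["regimen_drugs"] = drugs["regimen_drugs"].map(_canon)
    return DataRelease(key=key, tables=tables)


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------


def write_release(
    release: DataRelease,
    root_path: str | Path,
    layout: Layout | None = None,
) -> list[Path]:
    """Write a release to disk, byte-stably.

    Column order is fixed (required columns first, extras in stored order),
    rows are sorted on each table's key columns, and files end with a single
    newline — writing the same release twice yields identical bytes.
    Absent optional tables produce no file.  Returns the written paths.
    """
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    layout = layout or Layout()
    written: list[Path] = []
    for name in ALL_TABLES:
        df = release.tables.get(name)
        if df is None:
            continue
        path = root / layout.files[name]
        out = sort_table(name, df)
        required = REQUIRED_COLUMNS.get(name, [])
        cols = [c for c in required if c in out.columns] + [
            c for c in out.columns if c not in required
        ]
        out = out[cols]
        out.to_csv(path, sep=layout.seps[name], index=False, na_rep="", lineterminator="\n")
        written.append(path)
    return written


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One referential-integrity breach: rule, table, and offending keys."""

    rule_id: str
    table: str
    keys: tuple

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule_id}] {self.table}: {self.keys}"


RULE_IDS = (
    "record_id_dup",
    "pt_no_index_dx",
    "dx_orphan",
    "dx_key_dup",
    "regimen_orphan",
    "regimen_dup",
    "regimen_empty_drugs",
    "cpt_orphan",
    "sample_id_dup",
    "mutation_orphan",
    "fusion_orphan",
    "cna_orphan",
    "panel_dup",
)


def _dup_keys(df: pd.DataFrame, cols: list[str]) -> list[tuple]:
    dups = df[df.duplicated(cols, keep="first")]
    return [tuple(row) for row in dups[cols].itertuples(index=False)]


def validate_release(release: DataRelease) -> list[Violation]:
    """Check every relational invariant of the data model.

    Violations are data, not exceptions: each carries a rule identifier,
    the table concerned and the offending key values.  An empty list means
    the release is internally consistent.
    """
    v: list[Violation] = []
    t = release.tables
    pt, dxi, dxn = t["pt_char"], t["ca_dx_index"], t["ca_dx_non_index"]
    drugs, cpt = t["ca_drugs"], t["cpt"]

    for keys in _dup_keys(pt, ["record_id"]):
        v.append(Violation("record_id_dup", "pt_char", keys))

    # every patient was sequenced, so every patient carries >=1 index cancer
    with_dx = set(dxi["record_id"])
    for rid in pt.loc[~pt["record_id"].isin(with_dx), "record_id"]:
        v.append(Violation("pt_no_index_dx", "pt_char", (rid,)))

    known_pt = set(pt["record_id"])
    for name, dx in (("ca_dx_index", dxi), ("ca_dx_non_index", dxn)):
        for rid in dx.loc[~dx["record_id"].isin(known_pt), "record_id"]:
            v.append(Violation("dx_orphan", name, (rid,)))
        for keys in _dup_keys(dx, ["record_id", "ca_seq"]):
            v.append(Violation("dx_key_dup", name, keys))

    all_dx = pd.concat([dxi[["record_id", "ca_seq"]], dxn[["record_id", "ca_seq"]]])
    dx_keys = set(map(tuple, all_dx.itertuples(index=False)))
    index_dx_keys = set(map(tuple, dxi[["record_id", "ca_seq"]].itertuples(index=False)))

    for row in drugs[["record_id", "ca_seq"]].itertuples(index=False):
        if tuple(row) not in dx_keys:
            v.append(Violation("regimen_orphan", "ca_drugs", tuple(row)))
    for keys in _dup_keys(drugs, ["record_id", "ca_seq", "regimen_number"]):
        v.append(Violation("regimen_dup", "ca_drugs", keys))
    empty = drugs["regimen_drugs"].isna() | (
        drugs["regimen_drugs"].fillna("").str.strip() == ""
    )
    for row in drugs.loc[empty, ["record_id", "ca_seq", "regimen_number"]].itertuples(
        index=False
    ):
        v.append(Violation("regimen_empty_drugs", "ca_drugs", tuple(row)))

    # panel tests must link to an *index* cancer (sequencing defines index)
    for row in cpt[["record_id", "ca_seq", "sample_id"]].itertuples(index=False):
        if (row.record_id, row.ca_seq) not in index_dx_keys:
            v.append(Violation("cpt_orphan", "cpt", tuple(row)))
    for keys in _dup_keys(cpt, ["sample_id"]):
        v.append(Violation("sample_id_dup", "cpt", keys))

    known_samples = set(cpt["sample_id"])
    mut, fus, cna = t["mutations"], t["fusions"], t["cna"]
    for sid in mut.loc[
        ~mut["Tumor_Sample_Barcode"].isin(known_samples), "Tumor_Sample_Barcode"
    ]:
        v.append(Violation("mutation_orphan", "mutations", (sid,)))
    for sid in fus.loc[~fus["sample_id"].isin(known_samples), "sample_id"]:
        v.append(Violation("fusion_orphan", "fusions", (sid,)))
    for col in cna.columns:
        if col != "hugo_symbol" and col not in known_samples:
            v.append(Violation("cna_orphan", "cna", (col,)))

    for keys in _dup_keys(t["panels"], ["seq_assay_id", "hugo_symbol"]):
        v.append(Violation("panel_dup", "panels", keys))
    return v


# --------------------------------------------------------------------------
# Version registry
# --------------------------------------------------------------------------


def _registry_entries(registry: str | Path) -> list[dict]:
    raw = yaml.safe_load(Path(registry).read_text())
    if raw is None:
        return []
    entries = raw.get("releases", []) if isinstance(raw, dict) else raw
    out = []
    for e in entries:
        e = dict(e)
        e.setdefault(
            "access",
            "public" if str(e.get("version", "")).endswith("-public") else "consortium",
        )
        out.append(e)
    return out


def list_versions(registry: str | Path, most_recent: bool = False) -> pd.DataFrame:
    """List data-release versions recorded in a local registry file.

    The registry is a YAML file with one entry per release: cohort, version,
    release_date, an integer ``sequence`` ordering releases within a cohort,
    and optionally an ``access`` class (derived from the version suffix when
    absent).  With ``most_recent=True``, only the highest-sequence release
    per (cohort, access class) is kept — a cohort with both consortium and
    public releases keeps one of each.
    """
    entries = _registry_entries(registry)
    cols = ["cohort", "version", "release_date", "access"]
    if not entries:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(entries)
    if "sequence" not in df.columns:
        df["sequence"] = range(len(df))
    if most_recent:
        df = df.loc[df.groupby(["cohort", "access"])["sequence"].idxmax()]
    return df.sort_values(["cohort", "version"]).reset_index(drop=True)[cols]


def default_registry_path() -> Path:
    """Path of the registry shipped with the package."""
    return Path(__file__).parent / "data" / "registry.yaml"


# --------------------------------------------------------------------------
# Gene panels
# --------------------------------------------------------------------------


def panel_gene_count(release: DataRelease, seq_assay_id: str) -> int:
    """Number of genes on a sequencing panel; 0 (with a warning) if unknown."""
    panels = release.tables["panels"]
    genes = panels.loc[panels["seq_assay_id"] == seq_assay_id, "hugo_symbol"]
    if genes.empty:
        warnings.warn(f"unknown seq_assay_id {seq_assay_id!r}; gene count 0", stacklevel=2)
        return 0
    return int(genes.nunique())


def panel_gene_counts(panels: pd.DataFrame) -> dict[str, int]:
    """Gene-set size per assay ID, from the long panel-definition table."""
    return panels.groupby("seq_assay_id")["hugo_symbol"].nunique().to_dict()
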