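"""Generate relationally consistent synthetic data releases.

The generator emulates the shape of a real clinico-genomic release — one
patient table, index/non-index diagnoses, drug regimens, report tables,
cancer panel tests and the genomic files keyed by sample ID — with full
referential integrity, configurable missingness and realistic drug/panel
vocabularies.  It emulates only the relational and statistical structure
the pipeline consumes, not survival processes or genomic hotspot biology.

A single root seed feeds named substreams per table, so adding a table
never perturbs the others and every release is reproducible from its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import canonical_regimen_label, parse_drug_set
from .release import DataRelease, ReleaseKey, sort_table

__all__ = ["SyntheticParams", "synthesize_release", "inject_violation"]


# drug vocabulary: the platinum-doublet era NSCLC agents plus generic fillers
DEFAULT_DRUG_POOL = (
    "Carboplatin",
    "Cisplatin",
    "Pemetrexed Disodium",
    "Bevacizumab",
    "Nivolumab",
    "Pembrolizumab",
    "Docetaxel",
    "Paclitaxel",
    "Gemcitabine Hydrochloride",
    "Erlotinib Hydrochloride",
)

#: common multi-drug regimens sampled preferentially over random combinations
DEFAULT_REGIMEN_TEMPLATES = (
    ("Carboplatin", "Pemetrexed Disodium"),
    ("Cisplatin", "Pemetrexed Disodium"),
    ("Bevacizumab", "Carboplatin", "Pemetrexed Disodium"),
    ("Bevacizumab", "Cisplatin", "Pemetrexed Disodium"),
    ("Nivolumab",),
    ("Docetaxel",),
    ("Pembrolizumab",),
)

#: assay families per institution with plausible gene counts
DEFAULT_PANELS = (
    ("DFCI-ONCOPANEL-1", 275),
    ("DFCI-ONCOPANEL-2", 300),
    ("DFCI-ONCOPANEL-3", 447),
    ("MSK-IMPACT341", 341),
    ("MSK-IMPACT410", 410),
    ("MSK-IMPACT468", 468),
    ("VICC-01-SOLIDTUMOR", 322),
    ("VICC-01-T5A", 215),
    ("VICC-01-T7", 429),
)

_ONCOTREE_BY_HISTOLOGY = {
    "Adenocarcinoma": ("LUAD", "NSCLC"),
    "Squamous cell": ("LUSC", "NSCLC"),
}
_ONCOTREE_OTHER = ("NSCLC", "NSCLCPD", "LCLC", "LUAS")
_VARIANT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "In_Frame_Del",
)
_AA = "ACDEFGHIKLMNPQRSTVWY"

N_GENES_UNIVERSE = 500
N_CNA_GENES = 40


def _check_dist(name: str, dist: Mapping) -> None:
    if not dist:
        raise ValueError(f"{name} must be non-empty")
    probs = np.array(list(dist.values()), dtype=float)
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError(f"{name} probabilities must lie in [0, 1]")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities must sum to 1 (got {probs.sum()})")


@dataclass
class SyntheticParams:
    """Knobs of the synthetic release generator.

    Count distributions are ``{value: probability}`` mappings; categorical
    distributions likewise.  Defaults mimic a lung-cancer release: three
    contributing institutions, mostly stage III/IV disease, adenocarcinoma-
    dominant histology with a small missing fraction, platinum-doublet
    treatment templates and institution-specific sequencing panels.
    """

    n_patients: int = 100
    institution_weights: dict = field(
        default_factory=lambda: {"DFCI": 0.38, "MSK": 0.49, "VICC": 0.13}
    )
    stage_distribution: dict = field(
        default_factory=lambda: {
            "Stage I": 0.15,
            "Stage II": 0.15,
            "Stage III": 0.20,
            "Stage IV": 0.50,
        }
    )
    histology_distribution: dict = field(
        default_factory=lambda: {
            "Adenocarcinoma": 0.60,
            "Squamous cell": 0.25,
            "Other": 0.15,
        }
    )
    histology_missing_rate: float = 0.05
    drug_pool: tuple = DEFAULT_DRUG_POOL
    regimen_templates: tuple = DEFAULT_REGIMEN_TEMPLATES
    template_rate: float = 0.6
    regimens_per_dx: dict = field(
        default_factory=lambda: {0: 0.10, 1: 0.45, 2: 0.25, 3: 0.15, 4: 0.05}
    )
    drugs_per_regimen: dict = field(
        default_factory=lambda: {1: 0.45, 2: 0.35, 3: 0.20}
    )
    index_dx_per_patient: dict = field(default_factory=lambda: {1: 0.9, 2: 0.1})
    non_index_dx_rate: float = 0.15
    samples_per_patient: dict = field(
        default_factory=lambda: {1: 0.80, 2: 0.15, 3: 0.04, 4: 0.01}
    )
    sample_type_distribution: dict = field(
        default_factory=lambda: {"Primary": 0.60, "Metastasis": 0.35, "Local recurrence": 0.05}
    )
    report_day_missing_rate: float = 0.02
    panels: tuple = DEFAULT_PANELS
    mutations_per_sample: dict = field(
        default_factory=lambda: {0: 0.10, 1: 0.20, 2: 0.25, 3: 0.20, 4: 0.15, 5: 0.10}
    )
    fusions_per_sample: dict = field(default_factory=lambda: {0: 0.85, 1: 0.15})
    include_radiation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "institution_weights",
            "stage_distribution",
            "histology_distribution",
            "regimens_per_dx",
            "drugs_per_regimen",
            "index_dx_per_patient",
            "samples_per_patient",
            "sample_type_distribution",
            "mutations_per_sample",
            "fusions_per_sample",
        ):
            _check_dist(name, getattr(self, name))
        for name in ("histology_missing_rate", "report_day_missing_rate", "template_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if any(int(k) < 1 for k in self.index_dx_per_patient):
            raise ValueError("every patient needs at least one index diagnosis")
        if any(int(k) < 1 for k in self.samples_per_patient):
            raise ValueError("every patient needs at least one panel test")
        max_drugs = max(int(k) for k in self.drugs_per_regimen)
        if max_drugs > len(self.drug_pool):
            raise ValueError("drug pool smaller than the largest regimen size")
        if max_drugs < 1:
            raise ValueError("regimens must contain at least one drug")
        if not self.panels:
            raise ValueError("at least one sequencing panel is required")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


def _draw(rng: np.random.Generator, dist: Mapping):
    levels = list(dist.keys())
    probs = np.array(list(dist.values()), dtype=float)
    return levels[rng.choice(len(levels), p=probs / probs.sum())]


def _genes(n: int, rng: np.random.Generator) -> list[str]:
    universe = [f"GENE{j:04d}" for j in range(N_GENES_UNIVERSE)]
    idx = rng.choice(N_GENES_UNIVERSE, size=min(n, N_GENES_UNIVERSE), replace=False)
    return sorted(universe[i] for i in idx)


def synthesize_release(params: SyntheticParams | None = None, **kwargs) -> DataRelease:
    """Generate a complete synthetic release.

    The result always passes :func:`bpcpipe.release.validate_release`:
    every patient carries at least one index diagnosis and one cancer panel
    test (inclusion requires sequencing), regimen start days increase with
    regimen number, and all genomic records reference existing sample IDs.
    """
    if params is None:
        params = SyntheticParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either params or keyword overrides, not both")
    seed = params.seed

    # ---- panels -----------------------------------------------------------
    panel_rows = []
    panel_genes: dict[str, list[str]] = {}
    for assay, size in params.panels:
        genes = _genes(int(size), _rng(seed, f"panel:{assay}"))
        panel_genes[assay] = genes
        panel_rows.extend({"seq_assay_id": assay, "hugo_symbol": g} for g in genes)
    panels = pd.DataFrame(panel_rows, columns=["seq_assay_id", "hugo_symbol"])
    assays_by_inst: dict[str, list[str]] = {}
    for assay, _ in params.panels:
        assays_by_inst.setdefault(assay.split("-")[0], []).append(assay)
    all_assays = [a for a, _ in params.panels]

    # ---- patients ---------------------------------------------------------
    rng_pt = _rng(seed, "pt_char")
    institutions = [_draw(rng_pt, params.institution_weights) for _ in range(params.n_patients)]
    record_ids = [
        f"GENIE-{inst}-{i:06d}" for i, inst in enumerate(institutions, start=1)
    ]
    pt_char = pd.DataFrame(
        {
            "record_id": record_ids,
            "institution": institutions,
            "vital_status": [
                "Deceased" if rng_pt.random() < 0.4 else "Alive"
                for _ in record_ids
            ],
        }
    )

    # ---- diagnoses --------------------------------------------------------
    rng_dx = _rng(seed, "ca_dx")
    dx_rows, nonindex_rows = [], []
    dx_by_patient: dict[str, list[dict]] = {}
    for rid, inst in zip(record_ids, institutions):
        k = int(_draw(rng_dx, params.index_dx_per_patient))
        days = sorted(int(d) for d in rng_dx.integers(0, 2000, size=k))
        patient_dx = []
        for seq, day in enumerate(days, start=1):
            hist = (
                pd.NA
                if rng_dx.random() < params.histology_missing_rate
                else _draw(rng_dx, params.histology_distribution)
            )
            row = {
                "record_id": rid,
                "ca_seq": seq,
                "stage_dx": _draw(rng_dx, params.stage_distribution),
                "histology": hist,
                "dx_day": day,
            }
            dx_rows.append(row)
            patient_dx.append(row)
        dx_by_patient[rid] = patient_dx
        if rng_dx.random() < params.non_index_dx_rate:
            nonindex_rows.append(
                {
                    "record_id": rid,
                    "ca_seq": k + 1,
                    "stage_dx": _draw(rng_dx, params.stage_distribution),
                    "histology": _draw(rng_dx, params.histology_distribution),
                    "dx_day": int(rng_dx.integers(0, 2000)),
                }
            )
    ca_dx_index = pd.DataFrame(dx_rows)
    ca_dx_non_index = pd.DataFrame(
        nonindex_rows,
        columns=["record_id", "ca_seq", "stage_dx", "histology", "dx_day"],
    )

    # ---- drug regimens ----------------------------------------------------
    rng_rx = _rng(seed, "ca_drugs")
    drug_rows = []
    for rid in record_ids:
        regimen_counter = 0
        for dx in dx_by_patient[rid]:
            n_reg = int(_draw(rng_rx, params.regimens_per_dx))
            day = dx["dx_day"]
            for _ in range(n_reg):
                regimen_counter += 1
                day += int(rng_rx.integers(20, 180))
                if rng_rx.random() < params.template_rate:
                    drugs = params.regimen_templates[
                        rng_rx.integers(len(params.regimen_templates))
                    ]
                else:
                    n_drugs = int(_draw(rng_rx, params.drugs_per_regimen))
                    idx = rng_rx.choice(len(params.drug_pool), size=n_drugs, replace=False)
                    drugs = [params.drug_pool[i] for i in idx]
                end = (
                    pd.NA
                    if rng_rx.random() < 0.1
                    else day + int(rng_rx.integers(20, 150))
                )
                drug_rows.append(
                    {
                        "record_id": rid,
                        "ca_seq": dx["ca_seq"],
                        "regimen_number": regimen_counter,
                        "regimen_drugs": canonical_regimen_label(parse_drug_set(", ".join(drugs))),
                        "start_day": day,
                        "end_day": end,
                    }
                )
                day += int(rng_rx.integers(10, 60))
    ca_drugs = pd.DataFrame(
        drug_rows,
        columns=["record_id", "ca_seq", "regimen_number", "regimen_drugs", "start_day", "end_day"],
    )

    # ---- cancer panel tests ----------------------------------------------
    rng_cpt = _rng(seed, "cpt")
    cpt_rows = []
    for rid, inst in zip(record_ids, institutions):
        n_samples = int(_draw(rng_cpt, params.samples_per_patient))
        patient_dx = dx_by_patient[rid]
        for j in range(1, n_samples + 1):
            dx = patient_dx[int(rng_cpt.integers(len(patient_dx)))]
            hist = dx["histology"]
            if hist in _ONCOTREE_BY_HISTOLOGY:
                primary, fallback = _ONCOTREE_BY_HISTOLOGY[hist]
                code = primary if rng_cpt.random() < 0.9 else fallback
            else:
                code = _ONCOTREE_OTHER[int(rng_cpt.integers(len(_ONCOTREE_OTHER)))]
            assays = assays_by_inst.get(inst, all_assays)
            cpt_rows.append(
                {
                    "record_id": rid,
                    "ca_seq": dx["ca_seq"],
                    "sample_id": f"{rid}-T{j:02d}",
                    "oncotree_code": code,
                    "sample_type": _draw(rng_cpt, params.sample_type_distribution),
                    "seq_assay_id": assays[int(rng_cpt.integers(len(assays)))],
                    "report_day": (
                        pd.NA
                        if rng_cpt.random() < params.report_day_missing_rate
                        else dx["dx_day"] + int(rng_cpt.integers(5, 400))
                    ),
                }
            )
    cpt = pd.DataFrame(cpt_rows)

    # ---- PRISSMM report tables -------------------------------------------
    def _reports(stream: str, max_reports: int) -> pd.DataFrame:
        rng_r = _rng(seed, stream)
        rows = []
        for rid in record_ids:
            for _ in range(int(rng_r.integers(0, max_reports + 1))):
                rows.append({"record_id": rid, "report_day": int(rng_r.integers(0, 3000))})
        return pd.DataFrame(rows, columns=["record_id", "report_day"])

    prissmm_pathology = _reports("prissmm_pathology", 3)
    prissmm_imaging = _reports("prissmm_imaging", 5)
    prissmm_tm = _reports("prissmm_tm", 3)
    prissmm_md = _reports("prissmm_md", 4)

    ca_radtx = None
    if params.include_radiation:
        rng_rt = _rng(seed, "ca_radtx")
        rt_rows = [
            {
                "record_id": dx["record_id"],
                "ca_seq": dx["ca_seq"],
                "start_day": dx["dx_day"] + int(rng_rt.integers(10, 300)),
            }
            for dx in dx_rows
            if rng_rt.random() < 0.2
        ]
        ca_radtx = pd.DataFrame(rt_rows, columns=["record_id", "ca_seq", "start_day"])

    # ---- genomic files ----------------------------------------------------
    rng_mut = _rng(seed, "mutations")
    mut_rows = []
    for row in cpt_rows:
        genes = panel_genes[row["seq_assay_id"]]
        for _ in range(int(_draw(rng_mut, params.mutations_per_sample))):
            gene = genes[int(rng_mut.integers(len(genes)))]
            aa1, aa2 = (_AA[int(i)] for i in rng_mut.integers(len(_AA), size=2))
            mut_rows.append(
                {
                    "Hugo_Symbol": gene,
                    "Tumor_Sample_Barcode": row["sample_id"],
                    "Variant_Classification": _VARIANT_CLASSES[
                        int(rng_mut.integers(len(_VARIANT_CLASSES)))
                    ],
                    "HGVSp_Short": f"p.{aa1}{int(rng_mut.integers(1, 900))}{aa2}",
                }
            )
    mutations = pd.DataFrame(
        mut_rows,
        columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification", "HGVSp_Short"],
    )

    rng_fus = _rng(seed, "fusions")
    fus_rows = []
    for row in cpt_rows:
        genes = panel_genes[row["seq_assay_id"]]
        for _ in range(int(_draw(rng_fus, params.fusions_per_sample))):
            g1 = genes[int(rng_fus.integers(len(genes)))]
            g2 = genes[int(rng_fus.integers(len(genes)))]
            fus_rows.append(
                {
                    "hugo_symbol": g1,
                    "sample_id": row["sample_id"],
                    "fusion": f"{g1}-{g2} fusion",
                }
            )
    fusions = pd.DataFrame(fus_rows, columns=["hugo_symbol", "sample_id", "fusion"])

    rng_cna = _rng(seed, "cna")
    sample_ids = sorted(r["sample_id"] for r in cpt_rows)
    cna_genes = [f"GENE{j:04d}" for j in range(N_CNA_GENES)]
    calls = rng_cna.choice(
        [-2, -1, 0, 1, 2], size=(N_CNA_GENES, len(sample_ids)), p=[0.02, 0.08, 0.8, 0.08, 0.02]
    )
    cna = pd.DataFrame(calls, columns=sample_ids).astype("Int64")
    missing_mask = rng_cna.random(size=calls.shape) < 0.01
    cna = cna.mask(pd.DataFrame(missing_mask, columns=sample_ids))
    cna.insert(0, "hugo_symbol", cna_genes)

    tables = {
        "pt_char": pt_char,
        "ca_dx_index": ca_dx_index,
        "ca_dx_non_index": ca_dx_non_index,
        "ca_drugs": ca_drugs,
        "prissmm_pathology": prissmm_pathology,
        "prissmm_imaging": prissmm_imaging,
        "prissmm_tm": prissmm_tm,
        "prissmm_md": prissmm_md,
        "ca_radtx": ca_radtx,
        "cpt": cpt,
        "mutations": mutations,
        "fusions": fusions,
        "cna": cna,
        "panels": panels,
    }
    for name, df in tables.items():
        if df is None:
            continue
        for col, kind in (("ca_seq", "Int64"), ("regimen_number", "Int64")):
            if col in df.columns:
                df[col] = df[col].astype(kind)
        for col in ("dx_day", "start_day", "end_day", "report_day"):
            if col in df.columns:
                df[col] = df[col].astype("Int64")
        tables[name] = sort_table(name, df)

    key = ReleaseKey(cohort_name="SYN", version=f"v0-seed{seed}", release_date="synthetic")
    return DataRelease(key=key, tables=tables)


# --------------------------------------------------------------------------
# Violation injection (fixture mutator for validator tests)
# --------------------------------------------------------------------------


def inject_violation(release: DataRelease, rule_id: str) -> DataRelease:
    """Return a copy of the release violating exactly one named rule.

    Each mutation is engineered to trip its own rule and no other, so the
    validator can be tested for both sensitivity and specificity.
    """
    r = release.copy()
    t = r.tables

    def _append(name: str, row: pd.Series | pd.DataFrame) -> None:
        extra = row.to_frame().T if isinstance(row, pd.Series) else row
        t[name] = pd.concat([t[name], extra], ignore_index=True).astype(t[name].dtypes)

    if rule_id == "record_id_dup":
        _append("pt_char", t["pt_char"].iloc[0])
    elif rule_id == "pt_no_index_dx":
        row = t["pt_char"].iloc[0].copy()
        row["record_id"] = "GENIE-ZZZ-999999"
        _append("pt_char", row)
    elif rule_id == "dx_orphan":
        row = t["ca_dx_index"].iloc[0].copy()
        row["record_id"] = "GENIE-ZZZ-999999"
        row["ca_seq"] = 1
        _append("ca_dx_index", row)
    elif rule_id == "dx_key_dup":
        _append("ca_dx_index", t["ca_dx_index"].iloc[0])
    elif rule_id == "regimen_orphan":
        drugs = t["ca_drugs"]
        if drugs.empty:
            raise ValueError("release has no regimens to mutate")
        drugs.loc[drugs.index[0], "ca_seq"] = 999
    elif rule_id == "regimen_dup":
        if t["ca_drugs"].empty:
            raise ValueError("release has no regimens to mutate")
        _append("ca_drugs", t["ca_drugs"].iloc[0])
    elif rule_id == "regimen_empty_drugs":
        drugs = t["ca_drugs"]
        if drugs.empty:
            raise ValueError("release has no regimens to mutate")
        drugs.loc[drugs.index[0], "regimen_drugs"] = pd.NA
    elif rule_id == "cpt_orphan":
        t["cpt"].loc[t["cpt"].index[0], "ca_seq"] = 999
    elif rule_id == "sample_id_dup":
        # duplicate a full row: the duplicated sample still resolves for the
        # genomic files, so only the uniqueness rule trips
        _append("cpt", t["cpt"].iloc[0])
    elif rule_id == "mutation_orphan":
        mut = t["mutations"]
        if mut.empty:
            raise ValueError("release has no mutations to mutate")
        mut.loc[mut.index[0], "Tumor_Sample_Barcode"] = "GENIE-ZZZ-999999-T01"
    elif rule_id == "fusion_orphan":
        fus = t["fusions"]
        if fus.empty:
            raise ValueError("release has no fusions to mutate")
        fus.loc[fus.index[0], "sample_id"] = "GENIE-ZZZ-999999-T01"
    elif rule_id == "cna_orphan":
        cna = t["cna"]
        sample_cols = [c for c in cna.columns if c != "hugo_symbol"]
        if not sample_cols:
            raise ValueError("release has no CNA sample columns to mutate")
        t["cna"] = cna.rename(columns={sample_cols[0]: "GENIE-ZZZ-999999-T01"})
    elif rule_id == "panel_dup":
        _append("panels", t["panels"].iloc[0])
    else:
        raise ValueError(f"unknown rule_id {rule_id!r}")
    return r
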