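"""Release model: I/O round-trips, validation, registry, panels."""

import numpy as np
import pandas as pd
import pytest

from bpcpipe import (
    DataRelease,
    Layout,
    MissingTableError,
    ReleaseKey,
    SyntheticParams,
    default_registry_path,
    inject_violation,
    list_versions,
    load_release,
    panel_gene_count,
    synthesize_release,
    validate_release,
    write_release,
)
from bpcpipe.release import RULE_IDS


class TestRoundTrip:
    def test_write_then_load_reproduces_release(self, tmp_path, release):
        write_release(release, tmp_path)
        again = load_release(tmp_path, release.key)
        assert release.equals(again)

    def test_write_twice_is_byte_identical(self, tmp_path, small_release):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_release(small_release, d1)
        p2 = write_release(small_release, d2)
        assert [p.name for p in p1] == [p.name for p in p2]
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_absent_radiation_table_emits_no_file(self, tmp_path):
        r = synthesize_release(SyntheticParams(n_patients=10, seed=2, include_radiation=False))
        assert r.tables["ca_radtx"] is None
        written = write_release(r, tmp_path)
        assert not (tmp_path / Layout().files["ca_radtx"]).exists()
        loaded = load_release(tmp_path, r.key)
        assert loaded.tables["ca_radtx"] is None
        assert r.equals(loaded)

    def test_empty_directory_error_names_patient_table(self, tmp_path):
        with pytest.raises(MissingTableError, match="pt_char"):
            load_release(tmp_path, ReleaseKey("SYN", "v0"))

    def test_layout_pointing_cpt_at_missing_file_fails_naming_cpt(self, tmp_path, small_release):
        write_release(small_release, tmp_path)
        bad = Layout(files={"cpt": "no_such_file.csv"})
        with pytest.raises(MissingTableError, match="cpt"):
            load_release(tmp_path, small_release.key, bad)

    def test_malformed_integer_reports_file_and_line(self, tmp_path, small_release):
        write_release(small_release, tmp_path)
        path = tmp_path / Layout().files["cpt"]
        lines = path.read_text().splitlines()
        header = lines[0].split(",")
        day_idx = header.index("report_day")
        row = lines[1].split(",")
        row[day_idx] = "not-a-day"
        path.write_text("\n".join([lines[0], ",".join(row)] + lines[2:]) + "\n")
        with pytest.raises(ValueError, match=r"line 2.*report_day"):
            load_release(tmp_path, small_release.key)

    def test_extra_columns_warn_and_pass_through(self, tmp_path, small_release):
        write_release(small_release, tmp_path)
        path = tmp_path / Layout().files["ca_dx_index"]
        df = pd.read_csv(path, dtype=str)
        df["surprise"] = "x"
        df.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="surprise"):
            loaded = load_release(tmp_path, small_release.key)
        assert "surprise" in loaded.tables["ca_dx_index"].columns


class TestValidation:
    def test_synthetic_release_is_clean(self, release):
        assert validate_release(release) == []

    @pytest.mark.parametrize("rule_id", RULE_IDS)
    def test_each_injected_violation_is_the_only_one_reported(self, small_release, rule_id):
        mutated = inject_violation(small_release, rule_id)
        found = validate_release(mutated)
        assert [v.rule_id for v in found] == [rule_id]

    def test_injected_violations_carry_offending_keys(self, small_release):
        mutated = inject_violation(small_release, "sample_id_dup")
        (v,) = validate_release(mutated)
        assert v.table == "cpt"
        assert v.keys[0] in set(small_release.tables["cpt"]["sample_id"])

    def test_two_different_injections_both_reported(self, small_release):
        mutated = inject_violation(inject_violation(small_release, "cpt_orphan"), "record_id_dup")
        rules = sorted(v.rule_id for v in validate_release(mutated))
        assert rules == ["cpt_orphan", "record_id_dup"]

    def test_unknown_rule_id_rejected(self, small_release):
        with pytest.raises(ValueError, match="no_such_rule"):
            inject_violation(small_release, "no_such_rule")

    def test_random_mutations_detected_with_no_false_positives(self, small_release):
        rng = np.random.default_rng(5)
        for _ in range(60):
            rule = RULE_IDS[rng.integers(len(RULE_IDS))]
            found = validate_release(inject_violation(small_release, rule))
            assert [v.rule_id for v in found] == [rule]


class TestRegistry:
    def test_bundled_registry_most_recent_matches_published_listing(self):
        df = list_versions(default_registry_path(), most_recent=True)
        rows = set(map(tuple, df[["cohort", "version", "release_date"]].itertuples(index=False)))
        assert ("NSCLC", "v2.0-public", "May 2022") in rows
        assert ("NSCLC", "v2.1-consortium", "August 2021") in rows
        assert ("CRC", "v1.2-consortium", "August 2021") in rows
        assert ("BrCa", "v1.1-consortium", "October 2021") in rows

    def test_most_recent_is_subset_of_all(self):
        recent = list_versions(default_registry_path(), most_recent=True)
        full = list_versions(default_registry_path(), most_recent=False)
        recent_keys = set(map(tuple, recent[["cohort", "version"]].itertuples(index=False)))
        full_keys = set(map(tuple, full[["cohort", "version"]].itertuples(index=False)))
        assert recent_keys <= full_keys
        assert len(full) > len(recent)

    def test_empty_registry_yields_empty_table(self, tmp_path):
        path = tmp_path / "registry.yaml"
        path.write_text("releases: []\n")
        assert len(list_versions(path)) == 0

    def test_all_versions_returned_without_most_recent(self, tmp_path):
        path = tmp_path / "registry.yaml"
        path.write_text(
            "releases:\n"
            "  - {cohort: NSCLC, version: v1.1-consortium, release_date: A, sequence: 1}\n"
            "  - {cohort: NSCLC, version: v2.0-consortium, release_date: B, sequence: 2}\n"
            "  - {cohort: NSCLC, version: v2.1-consortium, release_date: C, sequence: 3}\n"
        )
        assert len(list_versions(path, most_recent=False)) == 3
        assert len(list_versions(path, most_recent=True)) == 1

    def test_rows_sorted_by_cohort_then_version(self):
        df = list_versions(default_registry_path())
        keys = list(map(tuple, df[["cohort", "version"]].itertuples(index=False)))
        assert keys == sorted(keys)


class TestPanels:
    def _release_with_panels(self, panels):
        r = synthesize_release(SyntheticParams(n_patients=5, seed=1))
        rows = [
            {"seq_assay_id": assay, "hugo_symbol": f"GENE{i:04d}"}
            for assay, n in panels
            for i in range(n)
        ]
        r.tables["panels"] = pd.DataFrame(rows)
        return r

    def test_panel_gene_count_is_set_size(self):
        r = self._release_with_panels([("BIG-468", 468)])
        assert panel_gene_count(r, "BIG-468") == 468

    def test_unknown_assay_counts_zero_with_warning(self, release):
        with pytest.warns(UserWarning, match="NOPE-1"):
            assert panel_gene_count(release, "NOPE-1") == 0

    def test_subset_panels_have_ordered_counts(self):
        r = self._release_with_panels([("SMALL", 100), ("LARGE", 300)])
        assert panel_gene_count(r, "SMALL") < panel_gene_count(r, "LARGE")
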