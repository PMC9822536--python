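"""Cohort construction: drug parsing, regimen ordering, filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpcpipe import (
    CohortFilter,
    SyntheticParams,
    assign_regimen_order,
    canonical_regimen_label,
    create_analytic_cohort,
    parse_drug_set,
    regimen_matches,
    synthesize_release,
)

from .conftest import assert_cohort_matches_oracle, random_filter

drug_names = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ -",
    min_size=1,
    max_size=20,
).filter(lambda s: s.strip(" -"))


class TestDrugParsing:
    def test_parses_three_drug_regimen_string(self):
        got = parse_drug_set("Bevacizumab, Carboplatin, Pemetrexed Disodium")
        assert got == {"bevacizumab", "carboplatin", "pemetrexed disodium"}

    def test_empty_string_gives_empty_set(self):
        assert parse_drug_set("") == frozenset()

    def test_order_case_and_spacing_do_not_matter(self):
        assert parse_drug_set("pemetrexed disodium,CARBOPLATIN") == parse_drug_set(
            "Carboplatin,  Pemetrexed Disodium"
        )

    def test_label_is_alphabetized_and_comma_joined(self):
        assert canonical_regimen_label({"carboplatin", "bevacizumab"}) == "Bevacizumab, Carboplatin"

    def test_singleton_label(self):
        assert canonical_regimen_label({"nivolumab"}) == "Nivolumab"

    def test_empty_set_has_no_label(self):
        with pytest.raises(ValueError):
            canonical_regimen_label(set())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(drug_names, min_size=1, max_size=5))
    def test_label_parse_label_is_a_fixed_point(self, drugs):
        label = canonical_regimen_label(parse_drug_set(", ".join(drugs)))
        assert canonical_regimen_label(parse_drug_set(label)) == label


class TestRegimenMatching:
    CASE_STUDY_QUERIES = [
        parse_drug_set("Carboplatin, Pemetrexed Disodium"),
        parse_drug_set("Cisplatin, Pemetrexed Disodium"),
        parse_drug_set("Bevacizumab, Carboplatin, Pemetrexed Disodium"),
        parse_drug_set("Bevacizumab, Cisplatin, Pemetrexed Disodium"),
    ]

    def test_doublet_matches_one_of_the_case_study_queries_exactly(self):
        regimen = {"carboplatin", "pemetrexed disodium"}
        assert regimen_matches(regimen, self.CASE_STUDY_QUERIES, "exact")

    def test_superset_fails_exact_but_passes_containing(self):
        regimen = {"carboplatin", "pemetrexed disodium", "nivolumab"}
        query = [{"carboplatin", "pemetrexed disodium"}]
        assert not regimen_matches(regimen, query, "exact")
        assert regimen_matches(regimen, query, "containing")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(drug_names, min_size=1, max_size=4))
    def test_any_regimen_matches_its_own_drug_set(self, drugs):
        canon = parse_drug_set(", ".join(drugs))
        assert regimen_matches(canon, [canon], "exact")
        assert regimen_matches(canon, [canon], "containing")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            regimen_matches({"a"}, [{"a"}], "fuzzy")


def _regimens(rows):
    return pd.DataFrame(
        rows, columns=["record_id", "ca_seq", "regimen_number", "regimen_drugs", "start_day", "end_day"]
    ).astype({"ca_seq": "Int64", "regimen_number": "Int64", "start_day": "Int64", "end_day": "Int64"})


class TestRegimenOrdering:
    def test_single_regimen_is_first_line(self):
        out = assign_regimen_order(_regimens([("p1", 1, 1, "Nivolumab", 10, 50)]))
        assert list(out["order_within_cancer"]) == [1]
        assert list(out["order_within_patient"]) == [1]

    def test_orders_follow_start_day_not_row_order(self):
        out = assign_regimen_order(
            _regimens([("p1", 1, 1, "A", 100, None), ("p1", 1, 2, "B", 50, None)])
        )
        assert list(out["order_within_cancer"]) == [2, 1]

    def test_orders_are_independent_across_diagnoses(self):
        out = assign_regimen_order(
            _regimens([("p1", 1, 1, "A", 10, None), ("p1", 2, 2, "B", 5, None)])
        )
        assert list(out["order_within_cancer"]) == [1, 1]
        assert sorted(out["order_within_patient"]) == [1, 2]

    def test_missing_start_day_sorts_last(self):
        out = assign_regimen_order(
            _regimens([("p1", 1, 1, "A", None, None), ("p1", 1, 2, "B", 500, None)])
        )
        assert list(out["order_within_cancer"]) == [2, 1]

    def test_duplicate_regimen_number_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assign_regimen_order(
                _regimens([("p1", 1, 1, "A", 10, None), ("p1", 1, 1, "B", 20, None)])
            )


class TestCreateAnalyticCohort:
    def test_empty_filter_returns_all_index_diagnoses(self, release):
        cohort = create_analytic_cohort(release, CohortFilter())
        assert len(cohort.cohort_ca_dx) == len(release.tables["ca_dx_index"])
        assert cohort.n_patients == len(release.tables["pt_char"])

    def test_missing_histology_fails_a_histology_filter(self):
        r = synthesize_release(SyntheticParams(n_patients=30, seed=3, histology_missing_rate=1.0))
        cohort = create_analytic_cohort(
            r, CohortFilter(stage_dx={"Stage IV"}, histology={"Adenocarcinoma"})
        )
        assert cohort.n_patients == 0

    def test_label_matching_is_case_insensitive(self, release):
        a = create_analytic_cohort(release, CohortFilter(histology={"Adenocarcinoma"}))
        b = create_analytic_cohort(release, CohortFilter(histology={"ADENOCARCINOMA"}))
        assert set(a.cohort_ca_dx["record_id"]) == set(b.cohort_ca_dx["record_id"])

    def test_unobserved_filter_level_warns_listing_observed(self, release):
        with pytest.warns(UserWarning, match="observed levels"):
            create_analytic_cohort(release, CohortFilter(stage_dx={"Stage IX"}))

    def test_adding_criteria_never_increases_patient_count(self, release):
        base = create_analytic_cohort(release, CohortFilter(stage_dx={"Stage IV"}))
        narrowed = create_analytic_cohort(
            release, CohortFilter(stage_dx={"Stage IV"}, histology={"Adenocarcinoma"})
        )
        assert narrowed.n_patients <= base.n_patients

    def test_containing_mode_is_superset_of_exact(self, release):
        q = ["Carboplatin, Pemetrexed Disodium"]
        exact = create_analytic_cohort(
            release, CohortFilter(regimen_queries=q, regimen_type="exact")
        )
        containing = create_analytic_cohort(
            release, CohortFilter(regimen_queries=q, regimen_type="containing")
        )
        assert set(exact.cohort_pt_char["record_id"]) <= set(
            containing.cohort_pt_char["record_id"]
        )

    def test_cohort_tables_join_to_retained_diagnoses(self, release):
        cohort = create_analytic_cohort(
            release, CohortFilter(regimen_queries=["Nivolumab"], regimen_type="containing")
        )
        dx_keys = set(
            map(tuple, cohort.cohort_ca_dx[["record_id", "ca_seq"]].itertuples(index=False))
        )
        for df in (cohort.cohort_ca_drugs, cohort.cohort_ngs):
            for key in zip(df["record_id"], df["ca_seq"]):
                assert key in dx_keys
        assert cohort.cohort_pt_char["record_id"].is_unique

    def test_first_line_platinum_doublet_filter_matches_oracle(self, release):
        filt = CohortFilter(
            stage_dx={"Stage IV"},
            histology={"Adenocarcinoma"},
            regimen_queries=[
                "Carboplatin, Pemetrexed Disodium",
                "Cisplatin, Pemetrexed Disodium",
                "Bevacizumab, Carboplatin, Pemetrexed Disodium",
                "Bevacizumab, Cisplatin, Pemetrexed Disodium",
            ],
            regimen_type="exact",
            regimen_order=1,
            regimen_order_type="within-cancer",
        )
        assert_cohort_matches_oracle(release, filt)

    def test_random_filters_match_brute_force(self):
        rng = np.random.default_rng(17)
        for i in range(25):
            r = synthesize_release(
                SyntheticParams(n_patients=int(rng.integers(10, 40)), seed=1000 + i)
            )
            assert_cohort_matches_oracle(r, random_filter(rng, r))
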