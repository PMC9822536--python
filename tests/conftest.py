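import numpy as np
import pandas as pd
import pytest

from bpcpipe import SyntheticParams, synthesize_release


@pytest.fixture(scope="session")
def release():
    """A mid-sized synthetic release shared by read-only tests."""
    return synthesize_release(SyntheticParams(n_patients=60, seed=11))


@pytest.fixture()
def small_release():
    """A fresh small release for tests that mutate tables."""
    return synthesize_release(SyntheticParams(n_patients=25, seed=7))


def random_filter(rng: np.random.Generator, release):
    """Draw a random CohortFilter from a release's observed vocabularies."""
    from bpcpipe import CohortFilter
    from bpcpipe.synthetic import DEFAULT_REGIMEN_TEMPLATES

    dx = release.tables["ca_dx_index"]
    pt = release.tables["pt_char"]

    def maybe_subset(values, p=0.5):
        values = sorted(set(v for v in values if not pd.isna(v)))
        if not values or rng.random() > p:
            return None
        k = int(rng.integers(1, len(values) + 1))
        return set(rng.choice(values, size=k, replace=False))

    queries = None
    if rng.random() < 0.6:
        n_q = int(rng.integers(1, 4))
        queries = [
            ", ".join(DEFAULT_REGIMEN_TEMPLATES[i])
            for i in rng.integers(len(DEFAULT_REGIMEN_TEMPLATES), size=n_q)
        ]
    order = None if rng.random() < 0.4 else int(rng.integers(1, 4))
    return CohortFilter(
        institutions=maybe_subset(pt["institution"], 0.4),
        stage_dx=maybe_subset(dx["stage_dx"], 0.5),
        histology=maybe_subset(dx["histology"], 0.5),
        index_ca_seq=maybe_subset(dx["ca_seq"], 0.2),
        regimen_queries=queries,
        regimen_type=str(rng.choice(["exact", "containing"])),
        regimen_order=order,
        regimen_order_type=str(rng.choice(["within-cancer", "within-regimen"])),
    )


def assert_cohort_matches_oracle(release, filt):
    """Compare create_analytic_cohort with the literal brute-force filter."""
    from bpcpipe import create_analytic_cohort

    from .oracles import brute_force_cohort

    expected = brute_force_cohort(release, filt)
    got = create_analytic_cohort(release, filt)
    got_dx = set(map(tuple, got.cohort_ca_dx[["record_id", "ca_seq"]].itertuples(index=False)))
    got_regs = set(
        map(
            tuple,
            got.cohort_ca_drugs[["record_id", "ca_seq", "regimen_number"]].itertuples(index=False),
        )
    )
    assert got_dx == expected["dx"]
    assert got_regs == expected["regimens"]
    assert set(got.cohort_ngs["sample_id"]) == expected["ngs"]
    assert set(got.cohort_pt_char["record_id"]) == expected["patients"]
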