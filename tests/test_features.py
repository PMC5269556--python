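"""Feature derivation: counting rules, the robust-claim predicate, carried-
forward neurologic codes, steroid matching, and table-level invariants."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_claims, make_demo, make_rx
from mdclaims.data_model import MD_3591, MD_ALL
from mdclaims.features import (
    PersonNotFoundError,
    completed_years,
    derive_features,
    derive_features_table,
    other_neuro_after,
    read_features,
    robust_claim_rule,
    steroid_flag,
    write_features,
)

EMPTY_RX = make_rx([])


def _d(day):
    return dt.date(2000, 1, 1) + dt.timedelta(days=day)


# ---------------------------------------------------------------------------
# robust-claim rule


@pytest.mark.parametrize(
    "claims,expected",
    [
        ([(_d(0), "inpatient")], True),  # one inpatient claim suffices
        ([(_d(0), "outpatient"), (_d(30), "outpatient")], True),  # gap of exactly 30
        ([(_d(0), "outpatient"), (_d(29), "outpatient")], False),  # 29-day gap fails
        ([(_d(0), "outpatient")], False),  # a single outpatient claim
        ([(_d(0), "clinic"), (_d(45), "outpatient")], True),  # clinic counts as ambulatory
        ([], False),
    ],
)
def test_robust_claim_rule_examples(claims, expected):
    assert robust_claim_rule(claims) is expected


def _robust_oracle(claims):
    """Exhaustive all-pairs oracle for the robust-claim rule."""
    if any(s == "inpatient" for _, s in claims):
        return True
    amb = [d for d, s in claims if s != "inpatient"]
    return any(abs((a - b).days) >= 30 for i, a in enumerate(amb) for b in amb[:i])


@given(
    st.lists(
        st.tuples(
            st.integers(0, 3650).map(_d),
            st.sampled_from(["inpatient", "outpatient", "clinic"]),
        ),
        max_size=10,
    )
)
def test_robust_claim_rule_agrees_with_pairwise_oracle(claims):
    assert robust_claim_rule(claims) == _robust_oracle(claims)


# ---------------------------------------------------------------------------
# carried-forward neurologic codes and the steroid flag


def test_other_neuro_after_strictly_after_first_md():
    first_md = pd.Timestamp("2001-03-01")
    after = make_claims([("A", "2001-06-01", "3450", "outpatient", "other", "medicaid")])
    same_day = make_claims([("A", "2001-03-01", "3450", "outpatient", "other", "medicaid")])
    only_md = make_claims([("A", "2001-06-01", "3591", "outpatient", "other", "medicaid")])
    assert other_neuro_after(after, first_md) is True
    assert other_neuro_after(same_day, first_md) is False
    assert other_neuro_after(only_md, first_md) is False


@pytest.mark.parametrize(
    "name,expected",
    [
        ("PREDNISONE 5MG TAB", True),
        ("methylprednisolone 4 mg", True),
        ("prednisolone syrup", True),
        ("deflazacort", False),
    ],
)
def test_steroid_flag_substring_match(name, expected):
    assert steroid_flag([name]) is expected
    assert steroid_flag(pd.Series([name, "albuterol"])) is expected


# ---------------------------------------------------------------------------
# per-person derivation


def test_same_day_duplicate_codes_count_one_date():
    claims = make_claims(
        [
            ("A", "2001-03-01", "3591", "outpatient", "neurology", "medicaid"),
            ("A", "2001-03-01", "3591", "outpatient", "neurology", "medicaid"),
        ]
    )
    demo = make_demo([("A", "male", "white", "1995-01-01")])
    row = derive_features(claims, EMPTY_RX, demo, "A")
    assert row["n_md_codes"] == 1
    assert row["n_3591"] == 1


def test_person_without_md_claims_yields_absent_marker():
    claims = make_claims([("A", "2001-03-01", "3450", "outpatient", "other", "medicaid")])
    demo = make_demo([("A", "male", "white", "1995-01-01")])
    assert derive_features(claims, EMPTY_RX, demo, "A") is None
    assert derive_features_table(claims, EMPTY_RX, demo).empty


def test_person_absent_from_demo_is_keyed_error():
    claims = make_claims([("A", "2001-03-01", "3591", "outpatient", "other", "medicaid")])
    demo = make_demo([("B", "male", "white", "1995-01-01")])
    with pytest.raises(PersonNotFoundError):
        derive_features_table(claims, EMPTY_RX, demo)


@pytest.mark.parametrize(
    "first_claim,age,group",
    [
        ("2008-06-14", 17, "le18"),  # day before the 18th birthday
        ("2008-06-15", 18, "le18"),  # 18 completed years is still "18 and younger"
        ("2009-06-15", 19, "gt18"),
    ],
)
def test_age_at_first_md_uses_completed_years(first_claim, age, group):
    claims = make_claims([("A", first_claim, "3591", "outpatient", "other", "medicaid")])
    demo = make_demo([("A", "male", "white", "1990-06-15")])
    row = derive_features(claims, EMPTY_RX, demo, "A")
    assert row["age_at_first_md"] == age
    assert row["age_group"] == group
    assert completed_years(dt.date(1990, 6, 15), dt.date.fromisoformat(first_claim)) == age


def test_only_claims_inside_window_contribute():
    claims = make_claims(
        [
            ("A", "1995-01-01", "3591", "inpatient", "other", "medicaid"),  # before window
            ("A", "2001-01-01", "3591", "outpatient", "other", "medicaid"),
        ]
    )
    demo = make_demo([("A", "male", "white", "1990-01-01")])
    row = derive_features(claims, EMPTY_RX, demo, "A")
    assert row["n_md_codes"] == 1
    assert not row["robust_claim"]  # the inpatient claim is outside the window


# ---------------------------------------------------------------------------
# table-level properties on the synthetic cohort


def test_derivation_is_permutation_invariant(small_cohort):
    claims = small_cohort.claims
    shuffled = claims.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = derive_features_table(claims, small_cohort.rx, small_cohort.demo)
    b = derive_features_table(shuffled, small_cohort.rx, small_cohort.demo)
    pd.testing.assert_frame_equal(a, b)


def test_count_invariants_between_total_and_per_code(small_cohort):
    f = derive_features_table(small_cohort.claims, small_cohort.rx, small_cohort.demo, MD_ALL)
    per_code = f[["n_3590", "n_3591", "n_35921"]]
    assert (f["n_md_codes"] <= per_code.sum(axis=1)).all()
    assert (f["n_md_codes"] >= per_code.max(axis=1)).all()
    assert (f["age_group"].eq("le18") == f["age_at_first_md"].le(18)).all()


def test_shrinking_window_never_increases_counts_or_flips_flags_on(small_cohort):
    full = derive_features_table(small_cohort.claims, small_cohort.rx, small_cohort.demo)
    narrow = derive_features_table(
        small_cohort.claims,
        small_cohort.rx,
        small_cohort.demo,
        window=(dt.date(2001, 1, 1), dt.date(2008, 12, 31)),
    )
    merged = narrow.merge(full, on="person_id", suffixes=("_narrow", "_full"))
    assert len(narrow) <= len(full)
    for col in ("n_md_codes", "n_3590", "n_3591", "n_35921"):
        assert (merged[f"{col}_narrow"] <= merged[f"{col}_full"]).all()
    for col in ("robust_claim", "neurologist_coded_md", "steroid_rx"):
        assert not (merged[f"{col}_narrow"] & ~merged[f"{col}_full"]).any()


def test_features_round_trip_through_csv(tmp_path, small_cohort):
    f = derive_features_table(small_cohort.claims, small_cohort.rx, small_cohort.demo, MD_3591)
    path = tmp_path / "features.csv"
    write_features(f, path)
    back = read_features(path, code_set_name="MD_3591")
    f2 = f.reset_index(drop=True)
    assert back.attrs["code_set"] == "MD_3591"
    pd.testing.assert_frame_equal(back, f2, check_dtype=False)


def test_robust_flag_matches_rule_recomputation(small_cohort):
    """Compositional check: the vectorized robust flag equals the per-person
    scalar rule applied to that person's in-window MD claims."""
    f = derive_features_table(small_cohort.claims, small_cohort.rx, small_cohort.demo, MD_ALL)
    claims = small_cohort.claims
    md = claims[claims["icd9_code"].isin(MD_ALL.codes)]
    rng = np.random.default_rng(0)
    sample = rng.choice(f["person_id"].to_numpy(), size=min(200, len(f)), replace=False)
    for pid in sample:
        sub = md[md["person_id"] == pid]
        expected = robust_claim_rule(list(zip(sub["service_date"], sub["setting"])))
        got = bool(f.loc[f["person_id"] == pid, "robust_claim"].iloc[0])
        assert got == expected
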