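"""Linkage partition, confusion counting, the PPV accuracy statistic, and
the stratified report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_claims, make_demo, make_gold, make_rx
from mdclaims.evaluation import (
    ConfusionCounts,
    MissingLabelError,
    UndefinedAccuracyError,
    accuracy,
    accuracy_exact,
    confusion,
    link_partition,
    load_published_strata,
    sensitivity,
    stratified_report,
)


# ---------------------------------------------------------------------------
# linkage


def test_link_partition_set_algebra():
    s = link_partition({"1", "2", "3"}, {"3", "4"})
    assert (s.n_both, s.n_passive_only, s.n_active_only) == (1, 2, 1)
    assert s.n_union == 4


def test_link_partition_disjoint_sets():
    assert link_partition({"a"}, {"b"}).n_both == 0


@given(
    st.lists(st.integers(0, 30), max_size=40),
    st.lists(st.integers(0, 30), max_size=40),
)
def test_link_partition_invariant_to_order_and_duplicates(p, a):
    base = link_partition(map(str, p), map(str, a))
    dup = link_partition(map(str, p + p[::-1]), map(str, a * 2))
    assert base == dup
    assert base.n_union == len(set(map(str, p)) | set(map(str, a)))


# ---------------------------------------------------------------------------
# confusion counts


def _gold_frame(labels):
    return make_gold(
        [
            (pid, True, conf, "dbmd" if conf else "not_md")
            for pid, conf in labels.items()
        ]
    )


def test_confusion_empty_flagged():
    gold = _gold_frame({"A": True, "B": False})
    c = confusion(set(), gold)
    assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 1, 1)


def test_confusion_perfect_flagging():
    gold = _gold_frame({"A": True, "B": True})
    c = confusion({"A", "B"}, gold)
    assert (c.fp, c.fn) == (0, 0)


def test_confusion_matches_brute_force_on_random_cohort():
    rng = np.random.default_rng(5)
    ids = [f"p{i}" for i in range(50)]
    conf = {i: bool(rng.random() < 0.4) for i in ids}
    flagged = {i for i in ids if rng.random() < 0.5}
    gold = _gold_frame(conf)
    c = confusion(flagged, gold, set(ids))
    # exhaustive membership oracle
    tp = sum(1 for i in ids if i in flagged and conf[i])
    fp = sum(1 for i in ids if i in flagged and not conf[i])
    fn = sum(1 for i in ids if i not in flagged and conf[i])
    tn = sum(1 for i in ids if i not in flagged and not conf[i])
    assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
    assert c.flagged == len(flagged)


def test_confusion_requires_labelled_universe():
    gold = _gold_frame({"A": True})
    with pytest.raises(MissingLabelError):
        confusion({"A"}, gold, {"A", "ghost"})
    with pytest.raises(ValueError):
        confusion({"outside"}, gold, {"A"})


def test_confusion_subtype_targets():
    gold = make_gold(
        [
            ("A", True, True, "dbmd"),
            ("B", True, True, "myotonic"),
            ("C", True, False, "not_md"),
        ]
    )
    c = confusion({"A", "B", "C"}, gold, target="dbmd")
    assert (c.tp, c.fp) == (1, 2)
    c = confusion({"A", "B", "C"}, gold, target="myotonic")
    assert (c.tp, c.fp) == (1, 2)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionCounts(tp=-1, fp=0, fn=0)


# ---------------------------------------------------------------------------
# accuracy (PPV)


@pytest.mark.parametrize(
    "tp,fp,expected",
    [(260, 277, 48.4), (46, 12, 79.3), (0, 5, 0.0), (1, 7, 12.5)],
)
def test_accuracy_reproduces_published_examples(tp, fp, expected):
    assert accuracy(ConfusionCounts(tp=tp, fp=fp, fn=0)) == expected


def test_accuracy_precision_and_half_up_rounding():
    # 384 of 2067 actively reviewed records confirmed: 18.58% at 2 decimals
    assert accuracy(ConfusionCounts(tp=384, fp=1683, fn=0), precision=2) == 18.58
    # half-up at the boundary: 1/8 = 12.5 -> 13 at 0 decimals
    assert accuracy(ConfusionCounts(tp=1, fp=7, fn=0), precision=0) == 13.0


def test_accuracy_undefined_when_nobody_flagged():
    with pytest.raises(UndefinedAccuracyError):
        accuracy(ConfusionCounts(tp=0, fp=0, fn=3))
    with pytest.raises(UndefinedAccuracyError):
        accuracy_exact(ConfusionCounts(tp=0, fp=0, fn=3))


@given(st.integers(0, 500), st.integers(0, 500), st.integers(1, 20))
def test_accuracy_bounded_and_scale_invariant(tp, fp, k):
    if tp + fp == 0:
        return
    base = accuracy_exact(ConfusionCounts(tp=tp, fp=fp, fn=0))
    assert 0.0 <= base <= 100.0
    scaled = accuracy_exact(ConfusionCounts(tp=k * tp, fp=k * fp, fn=0))
    assert scaled == pytest.approx(base)


def test_sensitivity_within_closed_universe():
    c = ConfusionCounts(tp=3, fp=1, fn=1, tn=5)
    assert sensitivity(c) == pytest.approx(75.0)


# ---------------------------------------------------------------------------
# stratified report


def test_report_on_empty_cohort_is_empty():
    empty_claims = make_claims([])
    report = stratified_report(empty_claims, make_rx([]), make_demo([]), make_gold([]))
    assert report.empty


def test_report_degenerate_all_confirmed_dbmd():
    claims = make_claims(
        [
            ("A", "2005-01-01", "3591", "inpatient", "neurology", "medicaid"),
            ("B", "2005-01-01", "3591", "inpatient", "neurology", "medicaid"),
        ]
    )
    demo = make_demo([("A", "male", "white", "1999-01-01"), ("B", "male", "white", "1999-01-01")])
    gold = make_gold([("A", True, True, "dbmd"), ("B", True, True, "dbmd")])
    report = stratified_report(
        claims, make_rx([]), demo, gold, targets=("any_md", "dbmd"), allow_empty=True
    )
    scored = report.dropna(subset=["accuracy_pct"])
    assert (scored["accuracy_pct"] == 100.0).all()


def test_report_matches_one_by_one_recomputation(small_cohort, small_universe):
    from mdclaims.algorithms import CATALOG, apply_algorithm
    from mdclaims.features import derive_features_table

    report = stratified_report(
        small_cohort.claims,
        small_cohort.rx,
        small_cohort.demo,
        small_cohort.gold,
        universe=small_universe,
        allow_empty=True,
    )
    assert list(report.columns) == ["algorithm", "target", "tp", "flagged", "accuracy_pct"]
    features_cache = {}
    for _, row in report.iterrows():
        spec = CATALOG[row["algorithm"]]
        key = spec.code_set.name
        if key not in features_cache:
            features_cache[key] = derive_features_table(
                small_cohort.claims, small_cohort.rx, small_cohort.demo, spec.code_set
            )
        flagged = apply_algorithm(features_cache[key], spec) & small_universe
        c = confusion(flagged, small_cohort.gold, small_universe, row["target"])
        assert c.tp == row["tp"] and c.flagged == row["flagged"]
        if c.flagged:
            assert accuracy(c) == row["accuracy_pct"]


def test_report_propagates_undefined_accuracy_by_default():
    # one person, female: the male-restricted stratum flags nobody
    claims = make_claims([("A", "2005-01-01", "3591", "inpatient", "neurology", "medicaid")])
    demo = make_demo([("A", "female", "white", "1999-01-01")])
    gold = make_gold([("A", True, True, "dbmd")])
    with pytest.raises(UndefinedAccuracyError):
        stratified_report(claims, make_rx([]), demo, gold)


def test_published_strata_fixture_is_consistent():
    strata = load_published_strata()
    assert len(strata) == 16
    assert (strata["tp"] <= strata["flagged"]).all()
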