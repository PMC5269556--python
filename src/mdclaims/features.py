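"""Collapse each person's claim/prescription/demographic history into the
per-person predictor vector the case-definition algorithms and the logistic
models consume.

Conventions (each is a documented interpretation of the source variables):

* "number of times a code was identified" is the count of **distinct service
  dates** bearing a code from the target set, guarding against same-day
  duplicate billing lines;
* the robust-claim rule is satisfied by one inpatient claim bearing the
  target code, or two non-inpatient claims on dates at least 30 calendar
  days apart (inclusive gap; clinic counts with outpatient);
* "another neurologic syndrome coded after MD" uses strict date inequality
  (same-day co-coding does not count as carried forward);
* the age boundary "18 years and younger" means completed years <= 18 at
  the first target-coded claim date;
* the corticosteroid flag is a case-insensitive substring match of
  "prednisone" or "prednisolone" in the drug name, so methylprednisolone
  matches.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .data_model import (
    MD_ALL,
    NEURO_CHAPTER,
    STUDY_WINDOW,
    CodeSet,
    Setting,
    code_mask,
)

__all__ = [
    "PersonNotFoundError",
    "FEATURE_COLUMNS",
    "STEROID_PATTERNS",
    "completed_years",
    "robust_claim_rule",
    "other_neuro_after",
    "steroid_flag",
    "derive_features_table",
    "derive_features",
    "write_features",
    "read_features",
]

#: Substrings matched (case-insensitively) against prescription drug names.
STEROID_PATTERNS = ("prednisone", "prednisolone")

#: Column order of the per-person feature table.
FEATURE_COLUMNS = [
    "person_id",
    "n_md_codes",
    "n_3590",
    "n_3591",
    "n_35921",
    "robust_claim",
    "sex",
    "race",
    "age_at_first_md",
    "age_group",
    "first_md_date",
    "neurologist_coded_md",
    "other_specialist_coded_md",
    "other_neuro_after",
    "steroid_rx",
    "in_study_window",
]

_BOOL_FEATURES = [
    "robust_claim",
    "neurologist_coded_md",
    "other_specialist_coded_md",
    "other_neuro_after",
    "steroid_rx",
    "in_study_window",
]

_OTHER_SPECIALTIES = frozenset({"cardiology", "genetics", "orthopedics", "other"})


class PersonNotFoundError(KeyError):
    """A person with claims is absent from the demographics table."""


def completed_years(birth: dt.date, on: dt.date) -> int:
    """Age in completed years on ``on`` for someone born on ``birth``."""
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


def _completed_years_vec(birth: pd.Series, on: pd.Series) -> pd.Series:
    years = on.dt.year - birth.dt.year
    before = (on.dt.month < birth.dt.month) | (
        (on.dt.month == birth.dt.month) & (on.dt.day < birth.dt.day)
    )
    return years - before.astype(int)


def robust_claim_rule(md_claims) -> bool:
    """Evidence-strength predicate on a person's target-coded claims.

    True iff there is at least one inpatient claim, or two non-inpatient
    claims whose dates differ by at least 30 days.  ``md_claims`` is either
    a DataFrame with ``service_date``/``setting`` columns or an iterable of
    ``(date, setting)`` pairs; it must already be restricted to claims
    bearing the target code set.  Empty input is False.
    """
    if isinstance(md_claims, pd.DataFrame):
        pairs = zip(pd.to_datetime(md_claims["service_date"]), md_claims["setting"])
    else:
        pairs = md_claims
    out_dates: list = []
    for date, setting in pairs:
        if str(getattr(setting, "value", setting)) == Setting.INPATIENT.value:
            return True
        out_dates.append(pd.Timestamp(date))
    if len(out_dates) < 2:
        return False
    return (max(out_dates) - min(out_dates)).days >= 30


def other_neuro_after(claims: pd.DataFrame, first_md_date) -> bool:
    """True iff a nervous-system-chapter (non-MD) code appears on a claim
    dated strictly after ``first_md_date``."""
    if claims.empty:
        return False
    neuro = code_mask(claims["icd9_code"], NEURO_CHAPTER)
    after = pd.to_datetime(claims["service_date"]) > pd.Timestamp(first_md_date)
    return bool((neuro & after).any())


def steroid_flag(drug_names: Iterable[str] | pd.Series) -> bool:
    """True iff any drug name contains a corticosteroid pattern."""
    if isinstance(drug_names, pd.Series):
        low = drug_names.str.lower()
        return bool(low.str.contains("|".join(STEROID_PATTERNS), regex=True).any())
    return any(p in str(name).lower() for name in drug_names for p in STEROID_PATTERNS)


def _window_bounds(window) -> tuple[pd.Timestamp, pd.Timestamp]:
    lo, hi = window
    lo, hi = pd.Timestamp(lo), pd.Timestamp(hi)
    if lo > hi:
        raise ValueError(f"invalid window: {lo.date()}..{hi.date()}")
    return lo, hi


def derive_features_table(
    claims: pd.DataFrame,
    rx: pd.DataFrame,
    demo: pd.DataFrame,
    code_set: CodeSet = MD_ALL,
    window=STUDY_WINDOW,
) -> pd.DataFrame:
    """Derive the predictor vector for every person with at least one
    in-window claim bearing a ``code_set`` code.

    Persons with no such claim are simply absent from the result (the
    absent-features marker); persons with claims but missing from ``demo``
    raise :class:`PersonNotFoundError`.  The result records its derivation
    code set and window in ``DataFrame.attrs`` so downstream algorithm
    application can verify compatibility.  Row order of the inputs never
    affects the output (rows are keyed and sorted by person_id).
    """
    lo, hi = _window_bounds(window)
    empty = pd.DataFrame(columns=FEATURE_COLUMNS)
    empty.attrs["code_set"] = code_set.name
    empty.attrs["window"] = (str(lo.date()), str(hi.date()))
    if claims.empty:
        return empty

    c = claims.loc[
        (pd.to_datetime(claims["service_date"]) >= lo)
        & (pd.to_datetime(claims["service_date"]) <= hi)
    ].copy()
    c["service_date"] = pd.to_datetime(c["service_date"])
    md = c.loc[code_mask(c["icd9_code"], code_set)]
    if md.empty:
        return empty

    persons = pd.Index(sorted(md["person_id"].unique()), name="person_id")
    missing = persons.difference(pd.Index(demo["person_id"]))
    if len(missing):
        raise PersonNotFoundError(
            f"persons with claims absent from demographics: {list(missing[:5])}"
        )

    g = md.groupby("person_id")
    n_md = g["service_date"].nunique().reindex(persons)
    first = g["service_date"].min().reindex(persons)

    # per-code distinct-date counts for the three built-in MD codes
    per_code = {}
    for code in ("3590", "3591", "35921"):
        cnt = (
            c.loc[c["icd9_code"].eq(code)]
            .groupby("person_id")["service_date"]
            .nunique()
            .reindex(persons)
            .fillna(0)
            .astype(int)
        )
        per_code[f"n_{code}"] = cnt

    inpatient_ids = set(md.loc[md["setting"].eq(Setting.INPATIENT.value), "person_id"])
    amb = md.loc[md["setting"].ne(Setting.INPATIENT.value)]
    span = amb.groupby("person_id")["service_date"].agg(["min", "max"])
    robust_out = ((span["max"] - span["min"]).dt.days >= 30).reindex(persons, fill_value=False)
    robust = persons.isin(inpatient_ids) | robust_out.to_numpy()

    sp = md["provider_specialty"]
    neuro_ids = set(md.loc[sp.eq("neurology"), "person_id"])
    otherspec_ids = set(md.loc[sp.isin(_OTHER_SPECIALTIES), "person_id"])

    # nervous-system-chapter codes carried strictly after the first MD code
    nc = c.loc[code_mask(c["icd9_code"], NEURO_CHAPTER), ["person_id", "service_date"]]
    if nc.empty:
        neuro_after = pd.Series(False, index=persons)
    else:
        nc = nc.join(first.rename("first_md"), on="person_id", how="inner")
        hits = nc.loc[nc["service_date"] > nc["first_md"], "person_id"]
        neuro_after = pd.Series(persons.isin(set(hits)), index=persons)

    if rx is not None and not rx.empty:
        r = rx.loc[
            (pd.to_datetime(rx["fill_date"]) >= lo) & (pd.to_datetime(rx["fill_date"]) <= hi)
        ]
        pat = "|".join(STEROID_PATTERNS)
        steroid_ids = set(r.loc[r["drug_name"].str.lower().str.contains(pat, regex=True), "person_id"])
    else:
        steroid_ids = set()

    d = demo.set_index("person_id").loc[persons]
    age = _completed_years_vec(pd.to_datetime(d["birth_date"]), first)

    out = pd.DataFrame(
        {
            "person_id": persons,
            "n_md_codes": n_md.to_numpy(int),
            "n_3590": per_code["n_3590"].to_numpy(),
            "n_3591": per_code["n_3591"].to_numpy(),
            "n_35921": per_code["n_35921"].to_numpy(),
            "robust_claim": np.asarray(robust, bool),
            "sex": d["sex"].to_numpy(),
            "race": d["race"].to_numpy(),
            "age_at_first_md": age.to_numpy(int),
            "age_group": np.where(age.to_numpy(int) <= 18, "le18", "gt18"),
            "first_md_date": first.to_numpy(),
            "neurologist_coded_md": persons.isin(neuro_ids),
            "other_specialist_coded_md": persons.isin(otherspec_ids),
            "other_neuro_after": neuro_after.to_numpy(bool),
            "steroid_rx": persons.isin(steroid_ids),
            "in_study_window": True,
        }
    ).reset_index(drop=True)
    out.attrs["code_set"] = code_set.name
    out.attrs["window"] = (str(lo.date()), str(hi.date()))
    return out


def derive_features(
    claims: pd.DataFrame,
    rx: pd.DataFrame,
    demo: pd.DataFrame,
    person_id: str,
    code_set: CodeSet = MD_ALL,
    window=STUDY_WINDOW,
):
    """Single-person feature derivation.

    Returns the person's feature row as a Series, or ``None`` (the
    absent-features marker) when the person has no in-window target-coded
    claim.  Raises :class:`PersonNotFoundError` if the person is missing
    from the demographics table.
    """
    if person_id not in set(demo["person_id"]):
        raise PersonNotFoundError(person_id)
    sub = claims.loc[claims["person_id"].eq(person_id)]
    tbl = derive_features_table(
        sub, rx.loc[rx["person_id"].eq(person_id)], demo, code_set, window
    )
    if tbl.empty:
        return None
    return tbl.iloc[0]


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV with booleans encoded 0/1."""
    out = features.loc[:, FEATURE_COLUMNS].copy()
    for c in _BOOL_FEATURES:
        out[c] = out[c].astype(int)
    out["first_md_date"] = pd.to_datetime(out["first_md_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_features(path: str | Path, code_set_name: str | None = None) -> pd.DataFrame:
    """Round-trip counterpart of :func:`write_features`."""
    df = pd.read_csv(path, dtype={"person_id": str})
    for c in _BOOL_FEATURES:
        df[c] = df[c].astype(bool)
    df["first_md_date"] = pd.to_datetime(df["first_md_date"])
    if code_set_name is not None:
        df.attrs["code_set"] = code_set_name
    return df
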