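"""Synthetic dual-surveillance cohort generator.

Emulates the statistical structure the ascertainment analysis assumes: a
statewide passive claims system and an active record-review system with
partial person overlap; a rare-disease setting where roughly half of the
code-flagged, linked persons are true cases; three MD ICD-9-CM codes with
differing specificity (359.21 highly specific for myotonic MD); and true
cases that accumulate systematically more coded encounters, more specialist
involvement, and more robust (inpatient / repeated-outpatient) claim
patterns than false positives.

False positives arise from the two mechanisms the published rules
implicitly target: *rule-out coding* (a single isolated MD code placed
while excluding the diagnosis) and *miscoding* of another neuromuscular
disease (moderate visit counts plus other nervous-system-chapter codes).

Every latent draw is recorded in a truth table so tests can condition on
it, and :func:`planted_ppv` computes the generator-implied positive
predictive value of any catalog algorithm by enumeration over the discrete
latent structure, for use as an oracle against empirical pipeline output.

Reproducibility: one master seed; each component (class assignment,
coverage, visit counts, per-encounter fields, demographics, prescriptions,
extra codes) draws from its own spawned substream in a fixed order, so
adding a table never perturbs existing draws.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import gammaln
from scipy.stats import binom as binom_dist
from scipy.stats import nbinom

from .algorithms import OTHER_SPECIALTIES, AlgorithmSpec, ConfigurationError
from .data_model import (
    MD_ALL,
    write_claims,
    write_demo,
    write_gold,
    write_rx,
)

__all__ = [
    "TRUE_CLASSES",
    "FP_CLASSES",
    "CLASSES",
    "SyntheticConfig",
    "CohortTables",
    "DEFAULT_PLANTED_BETA",
    "generate",
    "planted_ppv",
    "simulate_regression_cohort",
]

#: Latent classes for true cases (active-review subtype) ...
TRUE_CLASSES = ("dbmd", "myotonic", "congenital_other", "other_md", "unknown")
#: ... and for false positives (the generating mechanism).
FP_CLASSES = ("rule_out", "miscoded")
CLASSES = TRUE_CLASSES + FP_CLASSES

_MD_CODES = ("3590", "3591", "35921")
_SPECIALTIES = ("neurology", "cardiology", "genetics", "orthopedics", "other", "unknown")
_NEURO_FILLER_CODES = ("3230", "33390", "3439", "34500", "3569")
_STEROID_NAMES = (
    "prednisone 5 mg tab",
    "PREDNISOLONE 15MG/5ML syrup",
    "prednisone 10 mg tablet",
    "methylprednisolone 4 mg dosepak",
)
_OTHER_RX_NAMES = (
    "albuterol hfa inhaler",
    "lisinopril 10 mg tab",
    "amoxicillin 500 mg cap",
    "ibuprofen 600 mg tab",
)

#: Coefficients planted when simulating labelled cohorts for regression
#: recovery tests, in design-column order of :mod:`mdclaims.regression`.
DEFAULT_PLANTED_BETA = {
    "intercept": -1.6,
    "n_md_codes": 0.06,
    "robust_claim": 1.1,
    "male": 0.9,
    "race_african_american": -0.45,
    "race_other": -0.8,
    "neurologist_coded": 0.5,
    "other_specialist_coded": 0.55,
    "other_neuro_after": -0.6,
    "age": 0.012,
}


def _class_dict(true_val_or_map, fp_val_or_map=None) -> dict[str, float]:
    out = {}
    for c in CLASSES:
        src = true_val_or_map if c in TRUE_CLASSES else (fp_val_or_map or true_val_or_map)
        out[c] = src[c] if isinstance(src, dict) else src
    return out


class SyntheticConfig(BaseModel):
    """Generative parameters for the dual-surveillance cohort.

    Defaults reproduce the study conditions where stated (confirmed
    fraction among linked code-flagged persons, DBMD share of confirmed
    cases, overlap partition proportions, 1998-2012 window) and otherwise
    use values realistic for claims data on a rare neuromuscular disease.
    """

    model_config = ConfigDict(frozen=True)

    n_persons: int = Field(default=4765, ge=1)
    #: prevalence of confirmed MD among code-flagged persons (linked frame).
    p_true_case: float = Field(default=0.48, ge=0.0, le=1.0)
    #: subtype mix among confirmed cases; DBMD share echoes the study.
    subtype_mix: dict[str, float] = Field(
        default={
            "dbmd": 0.27,
            "myotonic": 0.18,
            "congenital_other": 0.10,
            "other_md": 0.20,
            "unknown": 0.25,
        }
    )
    fp_mechanism_mix: dict[str, float] = Field(default={"rule_out": 0.6, "miscoded": 0.4})
    #: per-encounter MD-code emission probabilities (3590, 3591, 35921);
    #: 359.21 is given high specificity (rarely emitted by false positives).
    code_emission: dict[str, tuple[float, float, float]] = Field(
        default={
            "dbmd": (0.06, 0.90, 0.04),
            "myotonic": (0.05, 0.10, 0.85),
            "congenital_other": (0.60, 0.35, 0.05),
            "other_md": (0.12, 0.83, 0.05),
            "unknown": (0.15, 0.75, 0.10),
            "rule_out": (0.30, 0.65, 0.05),
            "miscoded": (0.27, 0.70, 0.03),
        }
    )
    #: mean MD-coded encounters per person (zero-truncated negative
    #: binomial); true cases dominate false positives stochastically.
    visit_mean: dict[str, float] = Field(
        default={
            "dbmd": 9.0,
            "myotonic": 7.0,
            "congenital_other": 7.0,
            "other_md": 6.0,
            "unknown": 5.0,
            "rule_out": 1.3,
            "miscoded": 3.5,
        }
    )
    visit_dispersion: float = Field(default=1.2, gt=0.0)
    visit_max: int = Field(default=120, ge=2)
    #: per-encounter probability the claim is inpatient.
    p_inpatient: dict[str, float] = Field(
        default={
            "dbmd": 0.35,
            "myotonic": 0.28,
            "congenital_other": 0.30,
            "other_md": 0.25,
            "unknown": 0.22,
            "rule_out": 0.06,
            "miscoded": 0.10,
        }
    )
    #: per-encounter provider-specialty distribution, by truth status.
    specialty_probs: dict[str, dict[str, float]] = Field(
        default={
            "true": {
                "neurology": 0.45,
                "cardiology": 0.05,
                "genetics": 0.08,
                "orthopedics": 0.07,
                "other": 0.25,
                "unknown": 0.10,
            },
            "fp": {
                "neurology": 0.15,
                "cardiology": 0.04,
                "genetics": 0.02,
                "orthopedics": 0.05,
                "other": 0.56,
                "unknown": 0.18,
            },
        }
    )
    p_male: dict[str, float] = Field(
        default={
            "dbmd": 0.92,
            "myotonic": 0.50,
            "congenital_other": 0.55,
            "other_md": 0.55,
            "unknown": 0.60,
            "rule_out": 0.55,
            "miscoded": 0.50,
        }
    )
    #: probability of child onset (age <= 18 completed years at first code);
    #: the two-component age mixture populates both model strata.
    p_child: dict[str, float] = Field(
        default={
            "dbmd": 0.85,
            "myotonic": 0.30,
            "congenital_other": 0.80,
            "other_md": 0.30,
            "unknown": 0.40,
            "rule_out": 0.35,
            "miscoded": 0.30,
        }
    )
    p_steroid: dict[str, float] = Field(
        default={
            "dbmd": 0.65,
            "myotonic": 0.15,
            "congenital_other": 0.15,
            "other_md": 0.15,
            "unknown": 0.15,
            "rule_out": 0.05,
            "miscoded": 0.05,
        }
    )
    #: probability of carrying another nervous-system-chapter code after the
    #: first MD code (high for the miscoding mechanism).
    p_extra_neuro: dict[str, float] = Field(
        default={
            "dbmd": 0.30,
            "myotonic": 0.30,
            "congenital_other": 0.35,
            "other_md": 0.40,
            "unknown": 0.35,
            "rule_out": 0.15,
            "miscoded": 0.80,
        }
    )
    race_mix: dict[str, float] = Field(
        default={"white": 0.62, "african_american": 0.31, "other": 0.07}
    )
    #: (both, passive-only, active-only) coverage probabilities; defaults
    #: are the linked-partition proportions 537:2698:1530.
    overlap: tuple[float, float, float] = Field(
        default=(537 / 4765, 2698 / 4765, 1530 / 4765)
    )
    window: tuple[dt.date, dt.date] = Field(default=(dt.date(1998, 1, 1), dt.date(2012, 12, 31)))
    child_age_range: tuple[int, int] = Field(default=(0, 17))
    adult_age_range: tuple[int, int] = Field(default=(19, 60))
    planted_beta: dict[str, float] = Field(default=DEFAULT_PLANTED_BETA)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for name, mix in (
            ("subtype_mix", self.subtype_mix),
            ("fp_mechanism_mix", self.fp_mechanism_mix),
            ("race_mix", self.race_mix),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} must be a probability mixture summing to 1")
        if set(self.subtype_mix) != set(TRUE_CLASSES):
            raise ValueError(f"subtype_mix must cover {TRUE_CLASSES}")
        if set(self.fp_mechanism_mix) != set(FP_CLASSES):
            raise ValueError(f"fp_mechanism_mix must cover {FP_CLASSES}")
        if abs(sum(self.overlap) - 1.0) > 1e-9 or any(v < 0 for v in self.overlap):
            raise ValueError("overlap must be a probability mixture summing to 1")
        for field in ("code_emission", "visit_mean", "p_inpatient", "p_male", "p_child", "p_steroid", "p_extra_neuro"):
            d = getattr(self, field)
            if set(d) != set(CLASSES):
                raise ValueError(f"{field} must cover every latent class")
        for c, em in self.code_emission.items():
            if abs(sum(em) - 1.0) > 1e-9 or any(v < 0 for v in em):
                raise ValueError(f"code_emission[{c}] must sum to 1")
        for status, probs in self.specialty_probs.items():
            if set(probs) != set(_SPECIALTIES) or abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"specialty_probs[{status}] must cover {_SPECIALTIES} and sum to 1")
        if self.window[0] > self.window[1]:
            raise ValueError("window start after end")
        if set(self.planted_beta) and len(self.planted_beta) != 10:
            raise ValueError("planted_beta must have one entry per design column")
        return self

    @property
    def n_window_days(self) -> int:
        return (self.window[1] - self.window[0]).days + 1

    def specialty_dist(self, clazz: str) -> dict[str, float]:
        return self.specialty_probs["true" if clazz in TRUE_CLASSES else "fp"]


@dataclasses.dataclass
class CohortTables:
    """The generated tables plus the latent-truth metadata."""

    claims: pd.DataFrame
    rx: pd.DataFrame
    demo: pd.DataFrame
    gold: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "claims": out / "claims.csv",
            "rx": out / "rx.csv",
            "demo": out / "demo.csv",
            "gold": out / "gold.csv",
            "truth": out / "truth.csv",
        }
        write_claims(self.claims, paths["claims"])
        write_rx(self.rx, paths["rx"])
        write_demo(self.demo, paths["demo"])
        write_gold(self.gold, paths["gold"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _ztnb_pmf(mean: float, disp: float, kmax: int) -> np.ndarray:
    """Zero-truncated negative binomial pmf over 0..kmax (mass at 0 is 0);
    renormalized over 1..kmax so sampler and enumeration agree exactly."""
    r = disp
    p = r / (r + mean)
    pmf = nbinom.pmf(np.arange(kmax + 1), r, p)
    pmf[0] = 0.0
    return pmf / pmf.sum()


def _sample_from_pmf(rng: np.random.Generator, pmf: np.ndarray, size: int) -> np.ndarray:
    cum = np.cumsum(pmf)
    return np.searchsorted(cum, rng.random(size) * cum[-1], side="right")


def _distinct_dates(rng: np.random.Generator, person_index: np.ndarray, n_days: int) -> np.ndarray:
    """Sample encounter day offsets iid uniform, rejecting and redrawing
    whole persons until each person's dates are distinct (exact uniform
    over distinct date tuples)."""
    days = rng.integers(0, n_days, size=len(person_index))
    for _ in range(500):
        key = person_index.astype(np.int64) * n_days + days
        uniq, counts = np.unique(key, return_counts=True)
        if (counts == 1).all():
            return days
        offenders = np.unique(uniq[counts > 1] // n_days)
        mask = np.isin(person_index, offenders)
        days[mask] = rng.integers(0, n_days, size=int(mask.sum()))
    raise RuntimeError("date sampling failed to produce distinct dates")


def _subtract_years(dates: pd.Series, years: np.ndarray) -> pd.Series:
    """Vectorized calendar-year subtraction (Feb 29 clamps to Feb 28)."""
    y = dates.dt.year.to_numpy() - years
    m = dates.dt.month.to_numpy()
    d = dates.dt.day.to_numpy().copy()
    leap = (y % 4 == 0) & ((y % 100 != 0) | (y % 400 == 0))
    d[(m == 2) & (d == 29) & ~leap] = 28
    return pd.to_datetime(pd.DataFrame({"year": y, "month": m, "day": d}))


def _choice_rows(rng: np.random.Generator, prob_rows: np.ndarray, labels: tuple[str, ...]) -> np.ndarray:
    """Per-row categorical draw where each row has its own distribution."""
    cum = np.cumsum(prob_rows, axis=1)
    u = rng.random(len(prob_rows))
    idx = (u[:, None] > cum).sum(axis=1)
    return np.asarray(labels, dtype=object)[idx]


def generate(config: SyntheticConfig | None = None, seed: int | None = None) -> CohortTables:
    """Draw a full dual-surveillance cohort.

    Fully reproducible given (config, seed); ``seed`` overrides
    ``config.seed`` when supplied.  Passive tables (claims, rx, demo)
    contain only passive-covered persons, the gold table only
    active-covered ones, and the truth table everyone.
    """
    cfg = config or SyntheticConfig()
    master = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    streams = dict(
        zip(
            (
                "class",
                "coverage",
                "visits",
                "codes",
                "setting",
                "specialty",
                "dates",
                "demographics",
                "steroid",
                "rx",
                "neuro",
                "source",
            ),
            (np.random.default_rng(s) for s in ss.spawn(12)),
        )
    )
    n = cfg.n_persons
    persons = np.array([f"P{i:06d}" for i in range(1, n + 1)], dtype=object)

    # latent class: true-case subtype or false-positive mechanism
    rng = streams["class"]
    is_true = rng.random(n) < cfg.p_true_case
    subtype_labels = tuple(TRUE_CLASSES)
    sub_probs = np.array([cfg.subtype_mix[c] for c in subtype_labels])
    mech_labels = tuple(FP_CLASSES)
    mech_probs = np.array([cfg.fp_mechanism_mix[c] for c in mech_labels])
    clazz = np.empty(n, dtype=object)
    clazz[is_true] = _choice_rows(
        rng, np.tile(sub_probs, (int(is_true.sum()), 1)), subtype_labels
    )
    clazz[~is_true] = _choice_rows(
        rng, np.tile(mech_probs, (int((~is_true).sum()), 1)), mech_labels
    )

    coverage = _choice_rows(
        streams["coverage"],
        np.tile(np.asarray(cfg.overlap), (n, 1)),
        ("both", "passive_only", "active_only"),
    )

    # visit counts per person, from the class's zero-truncated NB
    rng = streams["visits"]
    pmfs = {c: _ztnb_pmf(cfg.visit_mean[c], cfg.visit_dispersion, cfg.visit_max) for c in CLASSES}
    u_visits = rng.random(n)
    k = np.empty(n, dtype=int)
    for c in CLASSES:
        m = clazz == c
        if m.any():
            cum = np.cumsum(pmfs[c])
            k[m] = np.searchsorted(cum, u_visits[m] * cum[-1], side="right")

    pidx = np.repeat(np.arange(n), k)
    total = len(pidx)

    emission = np.array([cfg.code_emission[c] for c in clazz], dtype=float)
    codes = _choice_rows(streams["codes"], emission[pidx], _MD_CODES)

    rng = streams["setting"]
    p_inp = np.array([cfg.p_inpatient[c] for c in clazz], dtype=float)
    inpat = rng.random(total) < p_inp[pidx]
    clinic = rng.random(total) < 0.25
    setting = np.where(inpat, "inpatient", np.where(clinic, "clinic", "outpatient"))

    spec_rows = np.array(
        [[cfg.specialty_dist(c)[s] for s in _SPECIALTIES] for c in clazz], dtype=float
    )
    specialty = _choice_rows(streams["specialty"], spec_rows[pidx], _SPECIALTIES)

    n_days = cfg.n_window_days
    days = _distinct_dates(streams["dates"], pidx, n_days)
    w0 = pd.Timestamp(cfg.window[0])
    dates = w0 + pd.to_timedelta(days, unit="D")
    first_day = np.full(n, n_days, dtype=int)
    np.minimum.at(first_day, pidx, days)

    rng = streams["source"]
    source = np.where(
        inpat, "hospital_discharge", np.where(rng.random(total) < 0.55, "medicaid", "private")
    )

    # demographics: sex, race, and age planted at the first MD-coded date
    rng = streams["demographics"]
    p_male = np.array([cfg.p_male[c] for c in clazz], dtype=float)
    male = rng.random(n) < p_male
    p_child = np.array([cfg.p_child[c] for c in clazz], dtype=float)
    child = rng.random(n) < p_child
    age = np.where(
        child,
        rng.integers(cfg.child_age_range[0], cfg.child_age_range[1] + 1, size=n),
        rng.integers(cfg.adult_age_range[0], cfg.adult_age_range[1] + 1, size=n),
    )
    race = _choice_rows(
        rng,
        np.tile(np.array([cfg.race_mix[r] for r in ("white", "african_american", "other")]), (n, 1)),
        ("white", "african_american", "other"),
    )
    first_date = w0 + pd.to_timedelta(first_day, unit="D")
    jitter = rng.integers(0, 364, size=n)
    birth = _subtract_years(pd.Series(first_date), age) - pd.to_timedelta(jitter, unit="D")

    # corticosteroid prescriptions plus unrelated background fills
    rng = streams["steroid"]
    p_ster = np.array([cfg.p_steroid[c] for c in clazz], dtype=float)
    steroid = rng.random(n) < p_ster
    rng = streams["rx"]
    rx_person: list[int] = []
    rx_day: list[int] = []
    rx_name: list[str] = []
    ster_idx = np.flatnonzero(steroid)
    n_fills = 1 + rng.integers(0, 3, size=len(ster_idx))
    for i, nf in zip(ster_idx, n_fills):
        lo = first_day[i]
        fill_days = rng.integers(lo, n_days, size=nf)
        names = rng.integers(0, len(_STEROID_NAMES), size=nf)
        rx_person.extend([i] * nf)
        rx_day.extend(fill_days.tolist())
        rx_name.extend(_STEROID_NAMES[j] for j in names)
    background = np.flatnonzero(rng.random(n) < 0.18)
    for i in background:
        lo = first_day[i]
        day = int(rng.integers(lo, n_days))
        rx_person.append(i)
        rx_day.append(day)
        rx_name.append(_OTHER_RX_NAMES[int(rng.integers(0, len(_OTHER_RX_NAMES)))])

    # extra nervous-system-chapter codes strictly after the first MD code
    rng = streams["neuro"]
    p_extra = np.array([cfg.p_extra_neuro[c] for c in clazz], dtype=float)
    extra = (rng.random(n) < p_extra) & (first_day < n_days - 1)
    ex_person: list[int] = []
    ex_day: list[int] = []
    ex_code: list[str] = []
    for i in np.flatnonzero(extra):
        cnt = 1 + int(rng.integers(0, 3))
        ds = rng.integers(first_day[i] + 1, n_days, size=cnt)
        cs = rng.integers(0, len(_NEURO_FILLER_CODES), size=cnt)
        ex_person.extend([i] * cnt)
        ex_day.extend(ds.tolist())
        ex_code.extend(_NEURO_FILLER_CODES[j] for j in cs)

    passive = coverage != "active_only"
    active = coverage != "passive_only"

    md_claims = pd.DataFrame(
        {
            "person_id": persons[pidx],
            "service_date": dates,
            "icd9_code": codes,
            "setting": setting,
            "provider_specialty": specialty,
            "source": source,
        }
    )
    if ex_person:
        ex_idx = np.asarray(ex_person)
        extra_claims = pd.DataFrame(
            {
                "person_id": persons[ex_idx],
                "service_date": w0 + pd.to_timedelta(np.asarray(ex_day), unit="D"),
                "icd9_code": np.asarray(ex_code, dtype=object),
                "setting": "outpatient",
                "provider_specialty": "other",
                "source": "medicaid",
            }
        )
        claims = pd.concat([md_claims, extra_claims], ignore_index=True)
    else:
        claims = md_claims
    claims = claims.loc[claims["person_id"].isin(persons[passive])]
    claims = claims.sort_values(["person_id", "service_date", "icd9_code"]).reset_index(drop=True)

    if rx_person:
        rx_idx = np.asarray(rx_person)
        rx = pd.DataFrame(
            {
                "person_id": persons[rx_idx],
                "fill_date": w0 + pd.to_timedelta(np.asarray(rx_day), unit="D"),
                "drug_name": np.asarray(rx_name, dtype=object),
            }
        )
        rx = rx.loc[rx["person_id"].isin(persons[passive])]
        rx = rx.sort_values(["person_id", "fill_date", "drug_name"]).reset_index(drop=True)
    else:
        rx = pd.DataFrame(columns=["person_id", "fill_date", "drug_name"])

    demo = pd.DataFrame(
        {
            "person_id": persons,
            "sex": np.where(male, "male", "female"),
            "race": race,
            "birth_date": birth.to_numpy(),
        }
    ).loc[passive].reset_index(drop=True)

    gold = pd.DataFrame(
        {
            "person_id": persons,
            "reviewed": True,
            "confirmed": is_true,
            "md_type": np.where(is_true, clazz, "not_md"),
        }
    ).loc[active].reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "person_id": persons,
            "coverage": coverage,
            "true_case": is_true,
            "latent_class": clazz,
            "n_encounters": k,
            "male": male,
            "child_onset": child,
            "age_at_first": age,
            "steroid": steroid,
            "extra_neuro": extra,
            "first_md_day": first_day,
        }
    )
    return CohortTables(claims=claims, rx=rx, demo=demo, gold=gold, truth=truth)


# ---------------------------------------------------------------------------
# Generator-implied PPV oracle


def _range_le_prob(j: int, r: int, n_days: int) -> float:
    """P(range <= r) for j distinct day offsets uniform over n_days values."""
    if j <= 1:
        return 1.0
    if j - 1 > r:
        return 0.0
    log_den = gammaln(n_days + 1) - gammaln(j + 1) - gammaln(n_days - j + 1)
    total = 0.0
    for s in range(j - 1, min(r, n_days - 1) + 1):
        log_num = (
            np.log(n_days - s)
            + gammaln(s)
            - gammaln(j - 1)
            - gammaln(s - j + 2)
        )
        total += float(np.exp(log_num - log_den))
    return min(total, 1.0)


def _robust_prob(j: int, p_inp: float, n_days: int) -> float:
    """P(robust-claim rule | j target-coded encounters on distinct days)."""
    if j == 0:
        return 0.0
    no_inp = (1.0 - p_inp) ** j
    return (1.0 - no_inp) + no_inp * (1.0 - _range_le_prob(j, 29, n_days))


def _flag_prob_given_class(cfg: SyntheticConfig, spec: AlgorithmSpec, clazz: str) -> float:
    """P(spec flags the person | latent class), by enumeration over the
    visit count and the thinned count of target-coded encounters."""
    if spec.code_set.root_range is not None or not set(spec.code_set.codes) <= set(_MD_CODES):
        raise ConfigurationError(
            f"planted_ppv supports only MD code sets, got {spec.code_set.name!r}"
        )
    em = dict(zip(_MD_CODES, cfg.code_emission[clazz]))
    q = sum(em[c] for c in spec.code_set.codes)
    kmax = cfg.visit_max
    pmf = _ztnb_pmf(cfg.visit_mean[clazz], cfg.visit_dispersion, kmax)

    sp = cfg.specialty_dist(clazz)
    ps = 0.0
    if spec.specialty_filter is not None:
        f = set(spec.specialty_filter)
        if "neurology" in f:
            ps += sp["neurology"]
        if f & OTHER_SPECIALTIES:
            ps += sum(sp[s] for s in OTHER_SPECIALTIES)

    j_grid = np.arange(kmax + 1)
    factor = (j_grid >= spec.min_code_count).astype(float)
    if spec.require_robust:
        factor = factor * np.array(
            [_robust_prob(int(j), cfg.p_inpatient[clazz], cfg.n_window_days) for j in j_grid]
        )
    if spec.specialty_filter is not None:
        factor = factor * (1.0 - (1.0 - ps) ** j_grid)

    p_claims = 0.0
    for kk in range(1, kmax + 1):
        if pmf[kk] == 0.0:
            continue
        bj = binom_dist.pmf(j_grid[: kk + 1], kk, q)
        p_claims += pmf[kk] * float(bj @ factor[: kk + 1])

    prob = p_claims
    if spec.sex_filter is not None:
        pm = cfg.p_male[clazz]
        prob *= pm if spec.sex_filter == "male" else 1.0 - pm
    if spec.age_group_filter is not None:
        pc = cfg.p_child[clazz]
        prob *= pc if spec.age_group_filter == "le18" else 1.0 - pc
    if spec.require_steroid:
        prob *= cfg.p_steroid[clazz]
    return prob


def planted_ppv(
    config: SyntheticConfig | None, spec: AlgorithmSpec, target: str = "any_md"
) -> float:
    """Generator-implied accuracy (PPV, percent) of ``spec``.

    Computed by exact enumeration over the discrete latent structure
    (latent class x visit count x per-encounter emissions); the 30-day-gap
    term uses the exact discrete range distribution of the without-
    replacement date sampler.  The age-group predicate uses the planted
    child-onset probability, which anchors age at the first any-MD-coded
    date (see the methods note for the one resulting approximation).
    """
    cfg = config or SyntheticConfig()
    if target == "any_md":
        target_classes = set(TRUE_CLASSES)
    elif target in ("dbmd", "myotonic"):
        target_classes = {target}
    else:
        raise ValueError(f"unknown target {target!r}")

    num = 0.0
    den = 0.0
    for c in CLASSES:
        if c in TRUE_CLASSES:
            w = cfg.p_true_case * cfg.subtype_mix[c]
        else:
            w = (1.0 - cfg.p_true_case) * cfg.fp_mechanism_mix[c]
        if w == 0.0:
            continue
        pf = w * _flag_prob_given_class(cfg, spec, c)
        den += pf
        if c in target_classes:
            num += pf
    if den == 0.0:
        raise ConfigurationError(f"spec {spec.name!r} has zero flag probability under the config")
    return 100.0 * num / den


# ---------------------------------------------------------------------------
# Labelled-cohort simulation for regression recovery


def simulate_regression_cohort(
    config: SyntheticConfig | None = None,
    n: int = 5000,
    seed: int = 0,
    beta: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Simulate (X, y) from the published design with a planted coefficient
    vector: covariates drawn from claims-realistic marginals, labels from
    Bernoulli(logit^-1(X beta))."""
    from .regression import DESIGN_COLUMNS  # local import to avoid a cycle

    cfg = config or SyntheticConfig()
    b = beta or cfg.planted_beta
    missing = [c for c in DESIGN_COLUMNS if c not in b]
    if missing:
        raise ValueError(f"planted beta missing entries: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(77,)))
    n_md = _sample_from_pmf(rng, _ztnb_pmf(6.0, cfg.visit_dispersion, cfg.visit_max), n)
    robust = rng.random(n) < 0.55
    male = rng.random(n) < 0.60
    race = _choice_rows(
        rng,
        np.tile(np.array([cfg.race_mix[r] for r in ("white", "african_american", "other")]), (n, 1)),
        ("white", "african_american", "other"),
    )
    neuro = rng.random(n) < 0.40
    otherspec = rng.random(n) < 0.35
    other_neuro = rng.random(n) < 0.30
    child = rng.random(n) < 0.50
    age = np.where(
        child,
        rng.integers(2, 19, size=n),
        rng.integers(19, 56, size=n),
    ).astype(float)
    X = np.column_stack(
        [
            np.ones(n),
            n_md.astype(float),
            robust.astype(float),
            male.astype(float),
            (race == "african_american").astype(float),
            (race == "other").astype(float),
            neuro.astype(float),
            otherspec.astype(float),
            other_neuro.astype(float),
            age,
        ]
    )
    bvec = np.array([b[c] for c in DESIGN_COLUMNS])
    from scipy.special import expit

    y = (rng.random(n) < expit(X @ bvec)).astype(float)
    return X, y, list(DESIGN_COLUMNS)
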