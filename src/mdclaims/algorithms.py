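"""Declarative case-definition rule engine and the built-in catalog of
ascertainment algorithms evaluated in the validation study.

An :class:`AlgorithmSpec` is a single conjunction of claims-derived
predicates: a diagnosis-code set with a minimum distinct-date count, an
optional robust-claim requirement, and optional demographic / specialty /
corticosteroid filters.  An all-default spec reduces to "at least one code
from the code set".  There is deliberately no disjunctive or nested boolean
DSL: every published stratum is a plain conjunction.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from types import MappingProxyType

import pandas as pd

from .data_model import MD_35921, MD_3591, MD_ALL, CodeSet

__all__ = [
    "ConfigurationError",
    "AlgorithmSpec",
    "OTHER_SPECIALTIES",
    "CATALOG",
    "apply_algorithm",
    "visit_tier_series",
    "spec_to_toml",
    "spec_from_toml",
]

#: Known non-neurology specialties ("other specialist" in the feature table).
OTHER_SPECIALTIES = frozenset({"cardiology", "genetics", "orthopedics", "other"})

_CODE_SETS = {cs.name: cs for cs in (MD_ALL, MD_3591, MD_35921)}
_CODE_SETS["MD_3590"] = CodeSet("MD_3590", frozenset({"3590"}))


class ConfigurationError(ValueError):
    """An AlgorithmSpec is inconsistent with the feature table."""


@dataclasses.dataclass(frozen=True)
class AlgorithmSpec:
    """One conjunctive case-definition rule.

    Parameters
    ----------
    code_set : target diagnosis codes; the feature table must have been
        derived with the same set.
    min_code_count : minimum number of distinct service dates bearing a
        code from ``code_set`` (>= 1).
    require_robust : require the robust-claim rule (one inpatient claim or
        two non-inpatient claims >= 30 days apart) on target-coded claims.
    sex_filter / age_group_filter : optional demographic predicates; the
        age group is judged at the first target-coded claim.
    specialty_filter : require at least one target-coded claim whose
        provider specialty is in the set; must be {neurology}, the
        other-specialist group, or their union ("unknown" never satisfies
        a specialty predicate).
    require_steroid : require a corticosteroid prescription.
    """

    name: str
    code_set: CodeSet
    min_code_count: int = 1
    require_robust: bool = False
    sex_filter: str | None = None
    age_group_filter: str | None = None
    specialty_filter: frozenset[str] | None = None
    require_steroid: bool = False

    def __post_init__(self) -> None:
        if self.min_code_count < 1:
            raise ValueError("min_code_count must be >= 1")
        if self.sex_filter not in (None, "male", "female"):
            raise ValueError(f"bad sex_filter: {self.sex_filter!r}")
        if self.age_group_filter not in (None, "le18", "gt18"):
            raise ValueError(f"bad age_group_filter: {self.age_group_filter!r}")
        if self.specialty_filter is not None:
            extra = set(self.specialty_filter) - ({"neurology"} | OTHER_SPECIALTIES)
            if extra or not self.specialty_filter:
                raise ValueError(f"bad specialty_filter: {sorted(self.specialty_filter or ())}")


def apply_algorithm(features: pd.DataFrame, spec: AlgorithmSpec) -> set[str]:
    """Flag every person satisfying all active predicates of ``spec``.

    Deterministic and idempotent; returns a set of person_ids.  Raises
    :class:`ConfigurationError` when the feature table was derived with a
    different code set, or when the specialty filter is finer than the two
    specialty flags the feature table records.
    """
    derived_with = features.attrs.get("code_set")
    if derived_with is not None and derived_with != spec.code_set.name:
        raise ConfigurationError(
            f"features derived with code set {derived_with!r}; "
            f"spec {spec.name!r} requires {spec.code_set.name!r}"
        )
    if features.empty:
        return set()

    mask = features["n_md_codes"].ge(spec.min_code_count)
    if spec.require_robust:
        mask &= features["robust_claim"].astype(bool)
    if spec.sex_filter is not None:
        mask &= features["sex"].eq(spec.sex_filter)
    if spec.age_group_filter is not None:
        mask &= features["age_group"].eq(spec.age_group_filter)
    if spec.specialty_filter is not None:
        f = set(spec.specialty_filter)
        others = f & OTHER_SPECIALTIES
        if others and others != OTHER_SPECIALTIES:
            raise ConfigurationError(
                "specialty_filter finer than the feature table records: "
                f"{sorted(others)}"
            )
        sp = pd.Series(False, index=features.index)
        if "neurology" in f:
            sp |= features["neurologist_coded_md"].astype(bool)
        if others:
            sp |= features["other_specialist_coded_md"].astype(bool)
        mask &= sp
    if spec.require_steroid:
        mask &= features["steroid_rx"].astype(bool)
    return set(features.loc[mask, "person_id"])


def visit_tier_series(
    features: pd.DataFrame, code: str = "3591", tiers: tuple[int, ...] = (1, 3, 10)
) -> dict[int, set[str]]:
    """Flagged sets at increasing minimum distinct-date counts of ``code``.

    Tier k flags persons with at least k distinct service dates bearing the
    code; the sets are nested (higher tier is a subset of any lower tier).
    """
    if list(tiers) != sorted(set(tiers)) or any(t < 1 for t in tiers):
        raise ValueError(f"tiers must be strictly increasing positive integers: {tiers}")
    col = f"n_{code}"
    if col not in features.columns:
        raise ConfigurationError(f"no per-code count column for code {code!r}")
    out: dict[int, set[str]] = {}
    for t in tiers:
        if features.empty:
            out[t] = set()
        else:
            out[t] = set(features.loc[features[col].ge(t), "person_id"])
    return out


def _catalog() -> MappingProxyType:
    specs = [
        AlgorithmSpec("ANY_MD_1CODE", MD_ALL),
        AlgorithmSpec("CODE_35921_1CODE", MD_35921),
        AlgorithmSpec("ANY_MD_ROBUST", MD_ALL, require_robust=True),
        AlgorithmSpec(
            "MALE_LE18_3591_ROBUST",
            MD_3591,
            require_robust=True,
            sex_filter="male",
            age_group_filter="le18",
        ),
        AlgorithmSpec("NEURO_CODED_3591", MD_3591, specialty_filter=frozenset({"neurology"})),
        AlgorithmSpec("OTHERSPEC_CODED_3591", MD_3591, specialty_filter=OTHER_SPECIALTIES),
        AlgorithmSpec("STEROID_3591", MD_3591, require_steroid=True),
        AlgorithmSpec("TIER_3591_1VISITS", MD_3591, min_code_count=1),
        AlgorithmSpec("TIER_3591_3VISITS", MD_3591, min_code_count=3),
        AlgorithmSpec("TIER_3591_10VISITS", MD_3591, min_code_count=10),
    ]
    return MappingProxyType({s.name: s for s in specs})


#: Immutable catalog of the ascertainment strata evaluated in the study:
#: any-MD single code, the high-specificity myotonic code, the robust-claim
#: restriction, the male/<=18/359.1/robust composite, specialty-coded 359.1,
#: steroid-prescription 359.1, and the 1/3/10-visit tiers of 359.1.
CATALOG: MappingProxyType = _catalog()


def spec_to_toml(spec: AlgorithmSpec) -> str:
    """Serialize a spec as flat key-value TOML."""
    lines = [
        f'name = "{spec.name}"',
        f'code_set = "{spec.code_set.name}"',
        f"min_code_count = {spec.min_code_count}",
        f"require_robust = {str(spec.require_robust).lower()}",
        f"require_steroid = {str(spec.require_steroid).lower()}",
    ]
    if spec.sex_filter:
        lines.append(f'sex_filter = "{spec.sex_filter}"')
    if spec.age_group_filter:
        lines.append(f'age_group_filter = "{spec.age_group_filter}"')
    if spec.specialty_filter:
        inner = ", ".join(f'"{s}"' for s in sorted(spec.specialty_filter))
        lines.append(f"specialty_filter = [{inner}]")
    return "\n".join(lines) + "\n"


def spec_from_toml(path: str | Path) -> AlgorithmSpec:
    """Load a spec from a flat key-value TOML file."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    cs_name = data.pop("code_set")
    if cs_name not in _CODE_SETS:
        raise ConfigurationError(f"unknown code_set {cs_name!r}")
    if "specialty_filter" in data:
        data["specialty_filter"] = frozenset(data["specialty_filter"])
    return AlgorithmSpec(code_set=_CODE_SETS[cs_name], **data)
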