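"""Domain types, ICD-9-CM code normalization, and delimited-text I/O.

The surveillance pipeline consumes four person-level tables, all UTF-8
comma-delimited text with a mandatory header row:

``claims.csv``
    one diagnosis code per row (multi-code encounters occupy several rows
    sharing person/date/setting): ``person_id, service_date, icd9_code,
    setting, provider_specialty, source``
``rx.csv``
    prescription fills: ``person_id, fill_date, drug_name``
``demo.csv``
    demographics, one row per person: ``person_id, sex, race, birth_date``
``gold.csv``
    active-surveillance review outcomes, one row per person:
    ``person_id, reviewed, confirmed, md_type``

Readers are strict but non-destructive: a row that violates a field domain
or a row-level invariant is diverted to a rejected-row report carrying the
offending column name, never silently coerced.  Structural problems
(missing mandatory column, duplicate person key in a keyed table) are hard
errors.  Dates are ISO-8601 throughout.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "Setting",
    "Specialty",
    "Source",
    "Sex",
    "Race",
    "MDType",
    "ClaimRecord",
    "RxRecord",
    "PersonDemo",
    "ActiveRecord",
    "CodeSet",
    "CodeError",
    "SchemaError",
    "DuplicateKeyError",
    "STUDY_WINDOW",
    "MD_ALL",
    "MD_3590",
    "MD_3591",
    "MD_35921",
    "NEURO_CHAPTER",
    "normalize_code",
    "code_mask",
    "read_claims",
    "read_rx",
    "read_demo",
    "read_gold",
    "write_claims",
    "write_rx",
    "write_demo",
    "write_gold",
    "iter_claim_records",
    "check_birth_precedes_claims",
]

#: Claims observation window used throughout the study: 1998-2012 inclusive.
STUDY_WINDOW = (dt.date(1998, 1, 1), dt.date(2012, 12, 31))


class Setting(str, enum.Enum):
    """Care setting recorded on a claim line."""

    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"
    CLINIC = "clinic"


class Specialty(str, enum.Enum):
    """Provider specialty noted on the claim; ``unknown`` is first-class."""

    NEUROLOGY = "neurology"
    CARDIOLOGY = "cardiology"
    GENETICS = "genetics"
    ORTHOPEDICS = "orthopedics"
    OTHER = "other"
    UNKNOWN = "unknown"


class Source(str, enum.Enum):
    """Administrative data system contributing the claim."""

    MEDICAID = "medicaid"
    PRIVATE = "private"
    HOSPITAL_DISCHARGE = "hospital_discharge"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Race(str, enum.Enum):
    WHITE = "white"
    AFRICAN_AMERICAN = "african_american"
    OTHER = "other"


class MDType(str, enum.Enum):
    """Muscular dystrophy subtype assigned during active record review."""

    DBMD = "dbmd"
    MYOTONIC = "myotonic"
    CONGENITAL_OTHER = "congenital_other"
    OTHER_MD = "other_md"
    UNKNOWN = "unknown"
    NOT_MD = "not_md"


def _values(e: type[enum.Enum]) -> frozenset[str]:
    return frozenset(m.value for m in e)


class CodeError(ValueError):
    """Raised for a diagnosis code that cannot be normalized."""


class SchemaError(ValueError):
    """Raised when an input file is structurally unusable."""


class DuplicateKeyError(ValueError):
    """Raised when a keyed table repeats a person_id."""


def normalize_code(raw: str) -> str:
    """Normalize an ICD-9-CM code: strip dots and whitespace, upper-case.

    ``"359.1"`` and ``"3591"`` normalize identically; codes are stored
    undotted (``"3591"``, ``"35921"``).  Raises :class:`CodeError` if the
    result is empty or not alphanumeric.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise CodeError(f"empty diagnosis code: {raw!r}")
    code = "".join(raw.split()).replace(".", "").upper()
    if not code or not code.isalnum():
        raise CodeError(f"unparseable diagnosis code: {raw!r}")
    return code


@dataclasses.dataclass(frozen=True)
class CodeSet:
    """A named set of normalized diagnosis codes.

    Membership is exact normalized-string equality against ``codes``,
    optionally extended by a 3-digit numeric root range (used for the
    nervous-system chapter 320-389), minus ``exclude``.  No prefix
    expansion is performed: the three MD codes are terminal as used here.
    """

    name: str
    codes: frozenset[str] = frozenset()
    root_range: tuple[int, int] | None = None
    exclude: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.codes and self.root_range is None:
            raise ValueError(f"CodeSet {self.name!r} is empty")

    def __contains__(self, code: str) -> bool:
        if code in self.exclude:
            return False
        if code in self.codes:
            return True
        if self.root_range is not None:
            root = code[:3]
            return root.isdigit() and self.root_range[0] <= int(root) <= self.root_range[1]
        return False


MD_3590 = CodeSet("MD_3590", frozenset({"3590"}))
MD_3591 = CodeSet("MD_3591", frozenset({"3591"}))
MD_35921 = CodeSet("MD_35921", frozenset({"35921"}))
#: The three muscular dystrophy ICD-9-CM codes: 359.0 congenital hereditary,
#: 359.1 hereditary progressive (includes Duchenne/Becker), 359.21 myotonic.
MD_ALL = CodeSet("MD_ALL", frozenset({"3590", "3591", "35921"}))
#: Diseases of the nervous system other than MD: numeric root 320-389.
NEURO_CHAPTER = CodeSet("NEURO_CHAPTER", root_range=(320, 389), exclude=MD_ALL.codes)


def code_mask(codes: pd.Series, code_set: CodeSet) -> pd.Series:
    """Vectorized CodeSet membership over a Series of normalized codes."""
    mask = codes.isin(code_set.codes)
    if code_set.root_range is not None:
        root = codes.str.slice(0, 3)
        lo, hi = code_set.root_range
        numeric = root.str.isdigit().fillna(False)
        val = pd.to_numeric(root.where(numeric), errors="coerce")
        mask = mask | (numeric & val.ge(lo) & val.le(hi))
    if len(code_set.exclude):
        mask = mask & ~codes.isin(code_set.exclude)
    return mask


# ---------------------------------------------------------------------------
# Typed record views


@dataclasses.dataclass(frozen=True)
class ClaimRecord:
    """One diagnosis-bearing encounter (possibly multiple codes)."""

    person_id: str
    service_date: dt.date
    icd9_codes: tuple[str, ...]
    setting: Setting
    provider_specialty: Specialty
    source: Source

    def __post_init__(self) -> None:
        if not self.icd9_codes:
            raise ValueError("ClaimRecord requires at least one code")


@dataclasses.dataclass(frozen=True)
class RxRecord:
    person_id: str
    fill_date: dt.date
    drug_name: str

    def __post_init__(self) -> None:
        if not self.drug_name:
            raise ValueError("RxRecord requires a drug name")


@dataclasses.dataclass(frozen=True)
class PersonDemo:
    person_id: str
    sex: Sex
    race: Race
    birth_date: dt.date


@dataclasses.dataclass(frozen=True)
class ActiveRecord:
    person_id: str
    reviewed: bool
    confirmed: bool
    md_type: MDType

    def __post_init__(self) -> None:
        if self.confirmed and not self.reviewed:
            raise ValueError("confirmed implies reviewed")
        if self.reviewed:
            if self.confirmed and self.md_type is MDType.NOT_MD:
                raise ValueError("confirmed record cannot be not_md")
            if not self.confirmed and self.md_type is not MDType.NOT_MD:
                raise ValueError("reviewed unconfirmed record must be not_md")


# ---------------------------------------------------------------------------
# Readers

CLAIMS_COLUMNS = ["person_id", "service_date", "icd9_code", "setting", "provider_specialty", "source"]
RX_COLUMNS = ["person_id", "fill_date", "drug_name"]
DEMO_COLUMNS = ["person_id", "sex", "race", "birth_date"]
GOLD_COLUMNS = ["person_id", "reviewed", "confirmed", "md_type"]

_BOOL_MAP = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def _load_raw(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return df.loc[:, columns].copy()


def _parse_id(s: pd.Series) -> tuple[pd.Series, pd.Series]:
    out = s.str.strip()
    return out, out.str.len().gt(0)


def _parse_date(s: pd.Series) -> tuple[pd.Series, pd.Series]:
    out = pd.to_datetime(s.str.strip(), format="%Y-%m-%d", errors="coerce")
    return out, out.notna()


def _parse_enum(e: type[enum.Enum]):
    allowed = _values(e)

    def parse(s: pd.Series) -> tuple[pd.Series, pd.Series]:
        out = s.str.strip().str.lower()
        return out, out.isin(allowed)

    return parse


def _parse_bool(s: pd.Series) -> tuple[pd.Series, pd.Series]:
    out = s.str.strip().str.lower().map(_BOOL_MAP)
    return out, out.notna()


def _parse_code(s: pd.Series) -> tuple[pd.Series, pd.Series]:
    out = s.str.replace(r"[\s.]+", "", regex=True).str.upper()
    ok = out.str.len().gt(0) & out.str.isalnum()
    return out, ok


def _parse_name(s: pd.Series) -> tuple[pd.Series, pd.Series]:
    out = s.str.strip()
    return out, out.str.len().gt(0)


def _parse_table(raw: pd.DataFrame, parsers: dict) -> tuple[pd.DataFrame, pd.Series]:
    """Apply per-column parsers; return parsed frame and per-row reject reason.

    The reason is the first offending column name, empty string for clean rows.
    """
    parsed = {}
    reason = pd.Series("", index=raw.index, dtype=str)
    for col, parser in parsers.items():
        val, ok = parser(raw[col])
        parsed[col] = val
        reason = reason.where(reason.ne("") | ok, col)
    return pd.DataFrame(parsed, index=raw.index), reason


def _split(raw: pd.DataFrame, parsed: pd.DataFrame, reason: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    bad = reason.ne("")
    rejected = raw.loc[bad].assign(reason=reason.loc[bad]).reset_index(drop=True)
    retained = parsed.loc[~bad].reset_index(drop=True)
    return retained, rejected


def read_claims(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a claims table; return (retained, rejected-with-reason).

    Retained rows carry normalized codes and parsed dates; retained plus
    rejected row counts always equal the input row count.
    """
    raw = _load_raw(path, CLAIMS_COLUMNS)
    parsed, reason = _parse_table(
        raw,
        {
            "person_id": _parse_id,
            "service_date": _parse_date,
            "icd9_code": _parse_code,
            "setting": _parse_enum(Setting),
            "provider_specialty": _parse_enum(Specialty),
            "source": _parse_enum(Source),
        },
    )
    return _split(raw, parsed, reason)


def read_rx(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a prescription table; see :func:`read_claims` for the contract."""
    raw = _load_raw(path, RX_COLUMNS)
    parsed, reason = _parse_table(
        raw,
        {"person_id": _parse_id, "fill_date": _parse_date, "drug_name": _parse_name},
    )
    return _split(raw, parsed, reason)


def read_demo(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a demographics table; duplicate person_id is a hard error."""
    raw = _load_raw(path, DEMO_COLUMNS)
    parsed, reason = _parse_table(
        raw,
        {
            "person_id": _parse_id,
            "sex": _parse_enum(Sex),
            "race": _parse_enum(Race),
            "birth_date": _parse_date,
        },
    )
    retained, rejected = _split(raw, parsed, reason)
    dup = retained["person_id"].duplicated()
    if dup.any():
        raise DuplicateKeyError(
            f"{path}: duplicate person_id in demographics: "
            f"{sorted(retained.loc[dup, 'person_id'].unique())[:5]}"
        )
    return retained, rejected


def read_gold(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the active-surveillance gold-standard table.

    Row-level invariants (confirmed implies reviewed; among reviewed rows
    md_type is ``not_md`` exactly when unconfirmed) divert violating rows to
    the rejected report.  Duplicate person_id is a hard error.
    """
    raw = _load_raw(path, GOLD_COLUMNS)
    parsed, reason = _parse_table(
        raw,
        {
            "person_id": _parse_id,
            "reviewed": _parse_bool,
            "confirmed": _parse_bool,
            "md_type": _parse_enum(MDType),
        },
    )
    clean = reason.eq("")
    conf = parsed["confirmed"].astype("boolean").fillna(False).astype(bool)
    rev = parsed["reviewed"].astype("boolean").fillna(False).astype(bool)
    mdt = parsed["md_type"].astype(str)
    bad_conf = clean & conf & ~rev
    reason = reason.where(~bad_conf, "confirmed")
    clean = reason.eq("")
    bad_type = clean & rev & ((conf & mdt.eq(MDType.NOT_MD.value)) | (~conf & mdt.ne(MDType.NOT_MD.value)))
    reason = reason.where(~bad_type, "md_type")
    retained, rejected = _split(raw, parsed, reason)
    if len(retained):
        retained = retained.astype({"reviewed": bool, "confirmed": bool})
    dup = retained["person_id"].duplicated()
    if dup.any():
        raise DuplicateKeyError(
            f"{path}: duplicate person_id in gold table: "
            f"{sorted(retained.loc[dup, 'person_id'].unique())[:5]}"
        )
    return retained, rejected


# ---------------------------------------------------------------------------
# Writers (round-trip counterparts of the readers)


def _write(df: pd.DataFrame, path: str | Path, date_cols: Iterable[str], bool_cols: Iterable[str] = ()) -> None:
    out = df.copy()
    for c in date_cols:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    for c in bool_cols:
        out[c] = out[c].map({True: "true", False: "false"})
    out.to_csv(path, index=False)


def write_claims(df: pd.DataFrame, path: str | Path) -> None:
    _write(df.loc[:, CLAIMS_COLUMNS], path, ["service_date"])


def write_rx(df: pd.DataFrame, path: str | Path) -> None:
    _write(df.loc[:, RX_COLUMNS], path, ["fill_date"])


def write_demo(df: pd.DataFrame, path: str | Path) -> None:
    _write(df.loc[:, DEMO_COLUMNS], path, ["birth_date"])


def write_gold(df: pd.DataFrame, path: str | Path) -> None:
    _write(df.loc[:, GOLD_COLUMNS], path, [], ["reviewed", "confirmed"])


def iter_claim_records(claims: pd.DataFrame) -> Iterator[ClaimRecord]:
    """Group claim rows into multi-code :class:`ClaimRecord` encounters."""
    keys = ["person_id", "service_date", "setting", "provider_specialty", "source"]
    for (pid, date, setting, spec, source), grp in claims.groupby(keys, sort=True):
        yield ClaimRecord(
            person_id=pid,
            service_date=pd.Timestamp(date).date(),
            icd9_codes=tuple(sorted(grp["icd9_code"])),
            setting=Setting(setting),
            provider_specialty=Specialty(spec),
            source=Source(source),
        )


def check_birth_precedes_claims(claims: pd.DataFrame, demo: pd.DataFrame) -> list[str]:
    """Return person_ids whose birth_date postdates any of their claims."""
    if claims.empty or demo.empty:
        return []
    first = claims.groupby("person_id")["service_date"].min()
    merged = demo.set_index("person_id")["birth_date"].to_frame().join(first, how="inner")
    bad = merged[merged["birth_date"] > merged["service_date"]]
    return sorted(bad.index)
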