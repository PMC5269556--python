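"""Linkage partition, confusion statistics, the study's accuracy measure
(positive predictive value), and stratified report generation.

The headline statistic is "accuracy" in the study's sense: true positives
divided by all flagged persons, i.e. PPV.  Sensitivity and the tn-based
metrics are available when a closed evaluation universe is supplied, but
reports label the PPV column ``accuracy_pct`` to match the published
tables.  The default evaluation frame is the set of persons found in both
the passive (claims) and active (record-review) systems, because subtype
confirmation exists only for actively reviewed persons.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .algorithms import CATALOG, AlgorithmSpec, apply_algorithm
from .data_model import STUDY_WINDOW
from .features import derive_features_table

__all__ = [
    "LinkageSummary",
    "ConfusionCounts",
    "UndefinedAccuracyError",
    "MissingLabelError",
    "TARGETS",
    "PUBLISHED_LINKAGE",
    "PUBLISHED_ACTIVE_REVIEW",
    "PUBLISHED_DBMD_AMONG_CONFIRMED",
    "link_partition",
    "gold_positive_ids",
    "confusion",
    "accuracy",
    "accuracy_exact",
    "sensitivity",
    "stratified_report",
    "load_published_strata",
]

#: Gold-standard target labels a stratum can be scored against.
TARGETS = ("any_md", "dbmd", "myotonic")


class UndefinedAccuracyError(ValueError):
    """Accuracy is undefined when nobody is flagged (tp + fp = 0)."""


class MissingLabelError(KeyError):
    """A universe member has no gold-standard label."""


@dataclasses.dataclass(frozen=True)
class LinkageSummary:
    """Partition of the union of passive and active person-id sets."""

    n_both: int
    n_passive_only: int
    n_active_only: int

    @property
    def n_union(self) -> int:
        return self.n_both + self.n_passive_only + self.n_active_only

    def as_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


#: Partition sizes reported for the statewide linkage (both / passive-only /
#: active-only); data outcomes of the original South Carolina systems, kept
#: as reference values for structure tests and reporting.
PUBLISHED_LINKAGE = LinkageSummary(n_both=537, n_passive_only=2698, n_active_only=1530)
#: (confirmed, reviewed) counts of the active record review.
PUBLISHED_ACTIVE_REVIEW = (384, 2067)
#: (DBMD, confirmed) counts among linked true cases.
PUBLISHED_DBMD_AMONG_CONFIRMED = (70, 260)


def link_partition(passive_ids: Iterable[str], active_ids: Iterable[str]) -> LinkageSummary:
    """Exact-key linkage partition: both / passive-only / active-only.

    Inputs are treated as sets, so ordering and duplicates are irrelevant;
    the three counts always sum to the size of the union.
    """
    p, a = set(passive_ids), set(active_ids)
    return LinkageSummary(
        n_both=len(p & a),
        n_passive_only=len(p - a),
        n_active_only=len(a - p),
    )


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """tp/fp/fn/tn against the gold standard; ``tn`` is ``None`` when no
    enumerable negative universe exists."""

    tp: int
    fp: int
    fn: int
    tn: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be non-negative")

    @property
    def flagged(self) -> int:
        return self.tp + self.fp


def gold_positive_ids(gold: pd.DataFrame, target: str = "any_md") -> set[str]:
    """Person-ids the gold standard labels positive for ``target``."""
    if target not in TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    conf = gold["confirmed"].astype(bool)
    if target == "any_md":
        mask = conf
    else:
        mask = conf & gold["md_type"].eq(target)
    return set(gold.loc[mask, "person_id"])


def confusion(
    flagged: Iterable[str],
    gold: pd.DataFrame,
    universe: Iterable[str] | None = None,
    target: str = "any_md",
) -> ConfusionCounts:
    """Score a flagged set against the gold standard over ``universe``.

    Every universe member must carry a gold label and the flagged set must
    lie inside the universe.  ``universe=None`` scores over all gold
    persons; callers evaluating the linked frame pass the intersection of
    passive and active person-ids explicitly.
    """
    f = set(flagged)
    labelled = set(gold["person_id"])
    u = labelled if universe is None else set(universe)
    if not f <= u:
        raise ValueError(f"flagged set is not contained in the universe ({len(f - u)} outside)")
    unlabelled = u - labelled
    if unlabelled:
        raise MissingLabelError(
            f"{len(unlabelled)} universe member(s) lack a gold label, e.g. {sorted(unlabelled)[:5]}"
        )
    pos = gold_positive_ids(gold, target) & u
    return ConfusionCounts(
        tp=len(f & pos),
        fp=len(f - pos),
        fn=len(pos - f),
        tn=len(u) - len(f | pos),
    )


def accuracy_exact(counts: ConfusionCounts) -> float:
    """Unrounded PPV on the percentage scale: 100 * tp / (tp + fp)."""
    if counts.flagged == 0:
        raise UndefinedAccuracyError("no persons flagged: accuracy undefined")
    return 100.0 * counts.tp / counts.flagged

def accuracy(counts: ConfusionCounts, precision: int = 1) -> float:
    """The study's accuracy statistic (PPV) as a percentage, rounded
    half-up to ``precision`` decimals (1 by default, 2 on request)."""
    if counts.flagged == 0:
        raise UndefinedAccuracyError("no persons flagged: accuracy undefined")
    exact = Decimal(100 * counts.tp) / Decimal(counts.flagged)
    q = Decimal(1).scaleb(-precision)
    return float(exact.quantize(q, rounding=ROUND_HALF_UP))


def sensitivity(counts: ConfusionCounts) -> float:
    """Recall within the evaluated universe: tp / (tp + fn)."""
    denom = counts.tp + counts.fn
    if denom == 0:
        raise UndefinedAccuracyError("no gold positives in universe: sensitivity undefined")
    return 100.0 * counts.tp / denom


def stratified_report(
    claims: pd.DataFrame,
    rx: pd.DataFrame,
    demo: pd.DataFrame,
    gold: pd.DataFrame,
    universe: Iterable[str] | None = None,
    catalog: Mapping[str, AlgorithmSpec] = CATALOG,
    targets: Iterable[str] = TARGETS,
    precision: int = 1,
    window=STUDY_WINDOW,
    allow_empty: bool = False,
) -> pd.DataFrame:
    """Score every catalog algorithm against every target label.

    Features are derived once per distinct code set appearing in the
    catalog; flagged sets are restricted to the evaluation universe before
    scoring.  One row per (algorithm, target) in catalog order, columns
    ``algorithm, target, tp, flagged, accuracy_pct``.  A stratum flagging
    nobody raises :class:`UndefinedAccuracyError` unless ``allow_empty``,
    in which case the row carries a missing accuracy.
    """
    u = set(gold["person_id"]) if universe is None else set(universe)
    columns = ["algorithm", "target", "tp", "flagged", "accuracy_pct"]
    if not u:
        return pd.DataFrame(columns=columns)
    features_by_set: dict[str, pd.DataFrame] = {}
    rows = []
    for name, spec in catalog.items():
        key = spec.code_set.name
        if key not in features_by_set:
            features_by_set[key] = derive_features_table(claims, rx, demo, spec.code_set, window)
        flagged = apply_algorithm(features_by_set[key], spec) & u
        for target in targets:
            counts = confusion(flagged, gold, u, target)
            if counts.flagged == 0 and allow_empty:
                acc: float | None = None
            else:
                if counts.flagged == 0:
                    raise UndefinedAccuracyError(
                        f"algorithm {name!r} flags nobody in the evaluation universe"
                    )
                acc = accuracy(counts, precision)
            rows.append(
                {
                    "algorithm": name,
                    "target": target,
                    "tp": counts.tp,
                    "flagged": counts.flagged,
                    "accuracy_pct": acc,
                }
            )
    return pd.DataFrame(rows, columns=columns)


def load_published_strata() -> pd.DataFrame:
    """Confusion counts (tp, flagged) and printed percentages for every
    published algorithm stratum, as transcribed reference values."""
    ref = importlib.resources.files("mdclaims") / "fixtures" / "published_strata.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
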