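"""Single entry point wiring the stages (simulate/load -> features ->
apply -> evaluate -> regress) with config, logging, and a reproducible
run manifest.

Outputs written under the run directory:

* ``report.csv`` — stratified accuracy (PPV) report for the catalog;
* ``regression_le18.csv`` / ``regression_gt18.csv`` — model tables in the
  published layout (parameter, referent, estimate, SE, p);
* ``linkage.json`` — both/passive-only/active-only partition;
* ``features.csv`` — the derived any-MD predictor table;
* ``manifest.json`` — package version, config hash, seed, and row counts
  at every stage; rerunning with the same inputs reproduces every output
  byte-for-byte.

No stage mutates its inputs.  Any stage failure aborts with the stage
name and the keyed cause.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .data_model import MD_ALL, STUDY_WINDOW, read_claims, read_demo, read_gold, read_rx
from .evaluation import link_partition, stratified_report
from .features import derive_features_table, write_features
from .regression import build_design, fit_logistic, fit_table, significance_screen
from .synthetic import CohortTables, SyntheticConfig, generate

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("mdclaims")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the keyed cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(BaseModel):
    """Pipeline run configuration: exactly one of ``input_dir`` (reading
    claims.csv/rx.csv/demo.csv/gold.csv) or ``simulate`` must be given."""

    model_config = ConfigDict(frozen=True)

    input_dir: str | None = None
    simulate: SyntheticConfig | None = None
    algorithms: list[str] | None = None
    universe: Literal["both", "all_gold"] = "both"
    out_dir: str = "mdclaims_run"
    precision: int = Field(default=1, ge=0, le=4)
    seed: int = Field(default=0, ge=0)
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "RunConfig":
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("supply exactly one of input_dir or simulate")
        return self


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return run

    return wrap


@_stage("load")
def _load(cfg: RunConfig, out: Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    counts: dict[str, int] = {}
    if cfg.simulate is not None:
        tables: CohortTables = generate(cfg.simulate, seed=cfg.seed)
        tables.write(out / "inputs")
        claims, rx, demo, gold = tables.claims, tables.rx, tables.demo, tables.gold
        counts["rejected_rows"] = 0
    else:
        src = Path(cfg.input_dir)
        claims, rej_c = read_claims(src / "claims.csv")
        rx, rej_r = read_rx(src / "rx.csv")
        demo, rej_d = read_demo(src / "demo.csv")
        gold, rej_g = read_gold(src / "gold.csv")
        rejected = sum(map(len, (rej_c, rej_r, rej_d, rej_g)))
        counts["rejected_rows"] = rejected
        if rejected:
            pd.concat(
                [df.assign(table=t) for t, df in
                 (("claims", rej_c), ("rx", rej_r), ("demo", rej_d), ("gold", rej_g)) if len(df)],
                ignore_index=True,
            ).to_csv(out / "rejected_rows.csv", index=False)
    counts.update(claims=len(claims), rx=len(rx), demo=len(demo), gold=len(gold))
    log.info("stage=load claims=%d rx=%d demo=%d gold=%d rejected=%d",
             len(claims), len(rx), len(demo), len(gold), counts["rejected_rows"])
    return claims, rx, demo, gold, counts


@_stage("linkage")
def _linkage(claims: pd.DataFrame, gold: pd.DataFrame, universe_kind: str, out: Path):
    passive = set(claims["person_id"])
    active = set(gold["person_id"])
    summary = link_partition(passive, active)
    (out / "linkage.json").write_text(json.dumps(summary.as_dict(), indent=2, sort_keys=True) + "\n")
    universe = (passive & active) if universe_kind == "both" else active
    log.info("stage=linkage both=%d passive_only=%d active_only=%d",
             summary.n_both, summary.n_passive_only, summary.n_active_only)
    return summary, universe


@_stage("features")
def _features(claims, rx, demo, out: Path) -> pd.DataFrame:
    feats = derive_features_table(claims, rx, demo, MD_ALL, STUDY_WINDOW)
    write_features(feats, out / "features.csv")
    log.info("stage=features persons=%d", len(feats))
    return feats


@_stage("evaluate")
def _evaluate(claims, rx, demo, gold, universe, cfg: RunConfig, out: Path) -> pd.DataFrame:
    from .algorithms import CATALOG

    catalog = CATALOG
    if cfg.algorithms is not None:
        unknown = [a for a in cfg.algorithms if a not in CATALOG]
        if unknown:
            raise KeyError(f"unknown algorithm(s): {unknown}")
        catalog = {a: CATALOG[a] for a in cfg.algorithms}
    report = stratified_report(
        claims, rx, demo, gold,
        universe=universe, catalog=catalog,
        precision=cfg.precision, allow_empty=True,
    )
    report.to_csv(out / "report.csv", index=False)
    log.info("stage=evaluate rows=%d", len(report))
    return report


@_stage("regress")
def _regress(feats: pd.DataFrame, gold: pd.DataFrame, universe: set, out: Path) -> dict[str, int]:
    labelled = feats.merge(gold[["person_id", "confirmed"]], on="person_id")
    labelled = labelled.loc[labelled["person_id"].isin(universe)]
    counts = {}
    for stratum in ("le18", "gt18"):
        X, y, names = build_design(labelled, stratum)
        fit = fit_logistic(X, y, names=names)
        table = fit_table(fit)
        table["significant"] = significance_screen(fit)["significant"]
        table.to_csv(out / f"regression_{stratum}.csv", index=False)
        counts[stratum] = fit.n_obs
        log.info("stage=regress stratum=%s n=%d iterations=%d", stratum, fit.n_obs, fit.n_iter)
    return counts


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written
    to ``manifest.json`` in the output directory)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    claims, rx, demo, gold, counts = _load(cfg, out)
    summary, universe = _linkage(claims, gold, cfg.universe, out)
    feats = _features(claims, rx, demo, out)
    report = _evaluate(claims, rx, demo, gold, universe, cfg, out)
    strata_n = _regress(feats, gold, universe, out)

    config_json = cfg.model_dump_json()
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "row_counts": {
            **counts,
            "linkage": summary.as_dict(),
            "universe": len(universe),
            "features": len(feats),
            "report_rows": len(report),
            "regression": strata_n,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
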