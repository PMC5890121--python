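"""Configurable end-to-end workflow: connect -> screen -> score -> model -> report.

One YAML (or JSON) config file drives every stage; unknown keys are rejected
so typos fail fast.  ``run`` produces a deterministic report bundle in the
output directory:

* ``screen.tsv``       — density grid over thresholds x networks (``N\\A`` for
  excluded cells), plus ``screens.json`` with the full per-cell verdicts
* ``efficiency.tsv``   — long-format per-participant global efficiencies
* ``es_report.tsv`` / ``cr_report.tsv`` — Table-style association grids
* ``summary.json``     — version, config hash, fit/convergence flags per cell
* ``run.log``          — logged provenance
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import CohortBehavior, read_behavior_csv
from .connectivity import (
    ConnectivityMatrix,
    correlation_matrix,
    read_connectivity_tsv,
    read_manifest,
    read_timeseries_csv,
    write_connectivity_tsv,
)
from .errors import ValidationError
from .parcellation import WBN, ParcellationSpec, bundled_parcellation, load_parcellation
from .screening import (
    NullModelConfig,
    ThresholdScreen,
    default_thresholds,
    participant_efficiencies,
    screen,
    screen_report,
    screens_long_table,
    write_efficiency_table,
)
from .sem import association_report, fit_acceptable, fit_sem

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "output_dir", "manifest", "behavior", "parcellation",
    "thresholds", "networks", "null_model", "sem", "efficiency_definition",
    "log_level",
}
_KNOWN_NULL_KEYS = {"n_random", "swaps_per_edge"}
_KNOWN_SEM_KEYS = {"robust_se", "include_na", "bonferroni_m"}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated stage parameters for a full pipeline run."""

    manifest: Path
    behavior: Path
    output_dir: Path
    parcellation: Path | None = None
    thresholds: tuple[float, ...] = tuple(default_thresholds())
    networks: tuple[str, ...] | None = None       # None = WBN + all subnetworks
    null_model: NullModelConfig = NullModelConfig()
    robust_se: bool = False
    include_na: bool = True
    bonferroni_m: int = 10
    efficiency_definition: str = "mean-inverse"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for t in self.thresholds:
            if not 0.15 <= t <= 0.85:
                raise ValidationError(
                    f"threshold {t} outside the supported sweep range [0.15, 0.85]"
                )
        if self.efficiency_definition not in ("mean-inverse", "inverse-mean"):
            raise ValidationError(
                f"unknown efficiency definition {self.efficiency_definition!r}"
            )
        if self.bonferroni_m < 1:
            raise ValidationError("bonferroni_m must be >= 1")

    def load_parcellation(self) -> ParcellationSpec:
        if self.parcellation is None:
            return bundled_parcellation()
        return load_parcellation(self.parcellation)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "manifest": str(self.manifest),
            "behavior": str(self.behavior),
            "parcellation": None if self.parcellation is None else str(self.parcellation),
            "thresholds": list(self.thresholds),
            "networks": None if self.networks is None else list(self.networks),
            "null_model": {"n_random": self.null_model.n_random,
                           "swaps_per_edge": self.null_model.swaps_per_edge},
            "sem": {"robust_se": self.robust_se, "include_na": self.include_na,
                    "bonferroni_m": self.bonferroni_m},
            "efficiency_definition": self.efficiency_definition,
            "log_level": self.log_level,
        }


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Parse and validate a YAML/JSON config file; unknown keys are rejected."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    null_raw = raw.get("null_model", {}) or {}
    if set(null_raw) - _KNOWN_NULL_KEYS:
        raise ValidationError(f"unknown null_model keys: {sorted(set(null_raw) - _KNOWN_NULL_KEYS)}")
    sem_raw = raw.get("sem", {}) or {}
    if set(sem_raw) - _KNOWN_SEM_KEYS:
        raise ValidationError(f"unknown sem keys: {sorted(set(sem_raw) - _KNOWN_SEM_KEYS)}")
    base = path.parent

    def _p(key):
        v = overrides.pop(key, None) or raw.get(key)
        if v is None:
            return None
        v = Path(v)
        return v if v.is_absolute() else (base / v)

    manifest = _p("manifest")
    behavior = _p("behavior")
    if manifest is None or behavior is None:
        raise ValidationError("config must provide 'manifest' and 'behavior' paths")
    kwargs = dict(
        manifest=manifest,
        behavior=behavior,
        parcellation=_p("parcellation"),
        output_dir=Path(overrides.pop("output_dir", None) or raw.get("output_dir", "ernet-out")),
        thresholds=tuple(raw.get("thresholds", default_thresholds())),
        networks=tuple(raw["networks"]) if raw.get("networks") else None,
        null_model=NullModelConfig(**null_raw),
        robust_se=bool(sem_raw.get("robust_se", False)),
        include_na=bool(sem_raw.get("include_na", True)),
        bonferroni_m=int(sem_raw.get("bonferroni_m", 10)),
        efficiency_definition=raw.get("efficiency_definition", "mean-inverse"),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_cohort_matrices(config: PipelineConfig):
    """Read the manifest and compute each participant's Fisher-z matrix."""
    manifest = read_manifest(config.manifest)
    ids, mats = [], []
    for _, row in manifest.iterrows():
        ts = read_timeseries_csv(row["path"], participant_id=row["participant_id"])
        mats.append(correlation_matrix(ts))
        ids.append(row["participant_id"])
    return ids, mats


def screens_to_json(screens: Sequence[ThresholdScreen]) -> list[dict]:
    return [
        {"network": s.network_id, "threshold": s.threshold, "k_mean": s.k_mean,
         "estimable": s.estimable, "sigma": s.sigma, "included": s.included,
         "density_pct": s.density_pct}
        for s in screens
    ]


def screens_from_json(cells: Sequence[Mapping]) -> list[ThresholdScreen]:
    return [
        ThresholdScreen(network_id=c["network"], threshold=c["threshold"],
                        k_mean=c["k_mean"], estimable=c["estimable"],
                        sigma=c["sigma"], included=c["included"],
                        density_pct=c["density_pct"])
        for c in cells
    ]


def run(config: PipelineConfig) -> dict:
    """Execute the full chain; returns a summary dict (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("ernet")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        return _run_stages(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, out: Path) -> dict:
    spec = config.load_parcellation()
    networks = list(config.networks) if config.networks else [WBN] + spec.networks
    log.info("pipeline start: version=%s config_hash=%s", __version__, _config_hash(config))

    ids, mats = load_cohort_matrices(config)
    behavior = read_behavior_csv(config.behavior)
    if list(behavior.participant_ids) != list(ids):
        raise ValidationError("behavior table and manifest participants do not match")
    log.info("loaded %d participants", len(ids))

    screens = screen(mats, spec, networks=networks,
                     thresholds=list(config.thresholds),
                     null_config=config.null_model, seed=config.seed)
    screen_report(screens, spec).to_csv(out / "screen.tsv", sep="\t")
    screens_long_table(screens).to_csv(out / "metrics.tsv", sep="\t", index=False,
                                       float_format="%.6f")
    (out / "screens.json").write_text(json.dumps(screens_to_json(screens), indent=1))
    n_included = sum(s.included for s in screens)
    log.info("screening: %d/%d cells included", n_included, len(screens))

    eff = participant_efficiencies(
        mats, spec, screens, participant_ids=ids,
        efficiency_definition=config.efficiency_definition,
    )
    write_efficiency_table(eff, out / "efficiency.tsv")

    bf = behavior.sem_frame()
    results = {}
    cell_summaries = []
    for s in screens:
        if not s.included:
            continue
        sel = eff[(eff.network == s.network_id) & (eff.threshold == s.threshold)]
        sel = sel.set_index("participant_id").loc[ids, "e_glob"].to_numpy()
        res = fit_sem(bf, sel, include_na=config.include_na, robust_se=config.robust_se)
        results[(s.network_id, round(s.threshold, 2))] = res
        ok, verdicts = fit_acceptable(res)
        cell_summaries.append({
            "network": s.network_id, "threshold": s.threshold,
            "converged": res.converged, "fit_acceptable": ok,
            "fit": dict(res.fit),
            "beta": dict(res.beta), "p_raw": dict(res.beta_pvalues),
        })
    log.info("fitted %d SEM cells", len(results))

    reports = {}
    for strategy, fname in (("ES", "es_report.tsv"), ("CR", "cr_report.tsv")):
        rep = association_report(results, strategy, networks,
                                 list(config.thresholds), m=config.bonferroni_m,
                                 spec=spec)
        rep.grid.to_csv(out / fname, sep="\t")
        rep.tidy.to_csv(out / fname.replace(".tsv", "_tidy.tsv"), sep="\t",
                        index=False, float_format="%.6f")
        reports[strategy] = rep

    summary = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "n_participants": len(ids),
        "n_cells_included": n_included,
        "cells": cell_summaries,
        "significant": {
            strategy: reports[strategy].tidy.loc[
                reports[strategy].tidy.significant, ["network", "threshold", "beta"]
            ].to_dict("records")
            for strategy in ("ES", "CR")
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    log.info("pipeline done")
    return summary
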