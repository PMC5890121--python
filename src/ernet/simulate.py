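"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a resting-state study cohort: per participant, a
``T x 264`` matrix of preprocessed regional BOLD time series (230 retained
volumes, mirroring 240 acquired minus 10 discarded) with block covariance
over the 10 subnetworks, and ordinal questionnaire responses driven by two
uncorrelated latent traits (expressive suppression and cognitive
reappraisal) plus an independent negative-affect latent.

Connectivity structure.  Uniform within-network correlation blocks would
collapse under group averaging into all-or-nothing threshold behaviour (every
within-block pair crosses a threshold together), leaving no graded density
profile and no clustered topology for the small-world screen.  Within each
network the target correlation therefore decays with distance between nodes
arranged on a ring (Gaussian kernel on chordal distance): nearest neighbours
correlate at ``rho_within`` (default 0.7), falling towards the
between-network floor ``rho_between`` (default 0.08).  Thresholded group
graphs are then lattice-like (high clustering, graded density, estimability
failing at high thresholds) — the regime the screening procedure expects.

Trait effect.  For each "affected" network the whole within-network block of
a participant's target correlations is shifted by ``beta_conn * es_latent``
(default map: FPN at -0.06 per SD of latent ES), so higher suppression
weakens within-network connectivity and the negative trait-efficiency
association must emerge through thresholding and graph metrics, exercising
the full causal chain.  Targets are clipped to [0.05, 0.95].

All randomness flows from one seed via ``numpy.random.SeedSequence``
children, so cohorts are exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import BEHAVIOR_COLUMNS, CohortBehavior, write_behavior_csv
from .connectivity import RegionalTimeSeries, write_timeseries_csv
from .errors import ValidationError
from .parcellation import ParcellationSpec, bundled_parcellation
from . import parcellation as _parc


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings; defaults mirror the emulated study design."""

    n_participants: int = 48
    acquired_volumes: int = 240
    discarded_volumes: int = 10
    tr_seconds: float = 2.0
    #: peak within-network correlation (nearest neighbours on the ring)
    rho_within: float = 0.7
    #: between-network (and within-network floor) correlation
    rho_between: float = 0.08
    #: Gaussian kernel length scale in chordal units of the unit ring
    kernel_length: float = 0.8
    #: network -> shift of within-network correlation per SD of latent ES
    effect_map: Mapping[str, float] = field(
        default_factory=lambda: {"FPN": -0.06}
    )
    #: standardized loading of each questionnaire item on its latent
    item_loading: float = 0.8
    #: ordinal mapping: item = clip(round(center + scale * continuous), lo, hi)
    es_item_center: float = 3.0
    cr_item_center: float = 5.0
    item_scale: float = 1.2
    na_item_center: float = 2.2
    na_item_scale: float = 0.9
    na_item_loading: float = 0.7
    age_mean: float = 22.77
    age_sd: float = 1.59
    male_fraction: float = 13 / 48
    seed: int = 0

    @property
    def t_volumes(self) -> int:
        """Retained volumes per participant (acquired minus discarded)."""
        return self.acquired_volumes - self.discarded_volumes

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("need at least 2 participants")
        if self.t_volumes < 3:
            raise ValidationError("need at least 3 retained volumes")
        if not 0.0 < self.item_loading < 1.0:
            raise ValidationError("item_loading must be in (0, 1)")
        if not 0.0 <= self.rho_between < self.rho_within < 1.0:
            raise ValidationError("need 0 <= rho_between < rho_within < 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_map"] = dict(self.effect_map)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**d)


@dataclass(frozen=True)
class CohortTruth:
    """Generating latents and parameters, carried for recovery scoring only."""

    es_latent: np.ndarray
    cr_latent: np.ndarray
    na_latent: np.ndarray
    age: np.ndarray
    gender: np.ndarray
    config: SimulationConfig


@dataclass(frozen=True)
class SyntheticCohort:
    behavior: CohortBehavior
    timeseries: list[RegionalTimeSeries]
    truth: CohortTruth


# --------------------------------------------------------------------------
# latents and questionnaire items
# --------------------------------------------------------------------------

def generate_latents(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Independent standard-normal ES/CR/NA latents plus age and gender.

    Returns a dict of arrays of length ``n_participants``.  ES, CR and NA are
    mutually independent by construction (the emulated cohort showed no
    ES-CR or ES-NA correlation); age is a rounded bounded normal; gender is
    Bernoulli(male_fraction) coded 1 = male.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_participants
    return {
        "es_latent": rng.standard_normal(n),
        "cr_latent": rng.standard_normal(n),
        "na_latent": rng.standard_normal(n),
        "age": np.clip(np.round(rng.normal(config.age_mean, config.age_sd, n)), 18, 30).astype(int),
        "gender": (rng.random(n) < config.male_fraction).astype(int),
    }


def _ordinal_items(latent, n_items, loading, center, scale, lo, hi, rng):
    n = latent.shape[0]
    resid_sd = np.sqrt(1.0 - loading ** 2)
    cont = loading * latent[:, None] + resid_sd * rng.standard_normal((n, n_items))
    return np.clip(np.round(center + scale * cont), lo, hi).astype(int)


def generate_items(latents: Mapping[str, np.ndarray], config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> CohortBehavior:
    """Ordinal questionnaire items from the latents (round-and-clip mapping)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    lam = config.item_loading
    es = _ordinal_items(latents["es_latent"], 4, lam, config.es_item_center,
                        config.item_scale, 1, 7, rng)
    cr = _ordinal_items(latents["cr_latent"], 6, lam, config.cr_item_center,
                        config.item_scale, 1, 7, rng)
    na = _ordinal_items(latents["na_latent"], 9, config.na_item_loading,
                        config.na_item_center, config.na_item_scale, 1, 5, rng)
    n = len(latents["es_latent"])
    df = pd.DataFrame({"participant_id": [f"sub-{i + 1:03d}" for i in range(n)]})
    for j in range(4):
        df[f"es{j + 1}"] = es[:, j]
    for j in range(6):
        df[f"cr{j + 1}"] = cr[:, j]
    for j in range(9):
        df[f"na{j + 1}"] = na[:, j]
    df["age"] = latents["age"]
    df["gender"] = latents["gender"]
    return CohortBehavior(df)


# --------------------------------------------------------------------------
# time series
# --------------------------------------------------------------------------

def _ring_kernel_block(m: int, config: SimulationConfig) -> np.ndarray:
    """Within-network target correlations: Gaussian kernel on ring chords."""
    angles = 2 * np.pi * np.arange(m) / m
    x = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    chord = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    k = np.exp(-((chord / config.kernel_length) ** 2))
    rho = config.rho_between + (config.rho_within - config.rho_between) * k
    np.fill_diagonal(rho, 1.0)
    return rho


def target_correlation(spec: ParcellationSpec, config: SimulationConfig,
                       es_latent: float = 0.0) -> np.ndarray:
    """Participant-level target correlation matrix over all nodes (id order).

    Between-network entries sit at ``rho_between``; within-network blocks
    follow the ring kernel, shifted by ``beta_conn * es_latent`` for networks
    in the effect map; off-diagonal targets clipped to [0.05, 0.95].
    """
    ids = sorted(spec.nodes["node_id"].tolist())
    pos = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)
    R = np.full((n, n), config.rho_between)
    for net in spec.networks:
        nodes = _parc.subnetwork_nodes(spec, net)
        idx = np.array([pos[i] for i in nodes])
        block = _ring_kernel_block(len(idx), config)
        shift = config.effect_map.get(net, 0.0) * es_latent
        off = ~np.eye(len(idx), dtype=bool)
        block = block.copy()
        block[off] = np.clip(block[off] + shift, 0.05, 0.95)
        R[np.ix_(idx, idx)] = block
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def _ensure_positive_definite(R: np.ndarray, max_shift: float = 0.05) -> np.ndarray:
    """Eigenvalue-clipping nearest-PD repair, re-normalized to unit diagonal.

    Errors out if the repair moves any entry by more than ``max_shift``.
    """
    w = np.linalg.eigvalsh(R)
    if w[0] > 1e-8:
        return R
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, 1e-6, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    shift = float(np.abs(fixed - R).max())
    if shift > max_shift:
        raise ValidationError(
            f"nearest-PD repair shifted a target correlation by {shift:.3f} > {max_shift}"
        )
    warnings.warn(f"target correlation repaired to positive definite (max shift {shift:.4f})")
    return fixed


def generate_timeseries(
    latents: Mapping[str, np.ndarray],
    config: SimulationConfig,
    spec: ParcellationSpec | None = None,
) -> list[RegionalTimeSeries]:
    """Multivariate-normal regional time series per participant.

    White noise across volumes (temporal autocorrelation is deliberately not
    modelled: correlation estimates depend only on the cross-regional
    covariance).  Participant ``i`` is seeded from SeedSequence(seed).spawn.
    """
    if spec is None:
        spec = bundled_parcellation()
    ids = sorted(spec.nodes["node_id"].tolist())
    n = config.n_participants
    seeds = np.random.SeedSequence(config.seed).spawn(3 + n)[3:]
    out = []
    for i in range(n):
        rng = np.random.default_rng(seeds[i])
        R = target_correlation(spec, config, es_latent=float(latents["es_latent"][i]))
        R = _ensure_positive_definite(R)
        chol = np.linalg.cholesky(R)
        noise = rng.standard_normal((config.t_volumes, len(ids)))
        values = noise @ chol.T
        out.append(
            RegionalTimeSeries(
                participant_id=f"sub-{i + 1:03d}", values=values,
                node_ids=tuple(ids), tr_seconds=config.tr_seconds,
            )
        )
    return out


def generate_cohort(config: SimulationConfig,
                    spec: ParcellationSpec | None = None) -> SyntheticCohort:
    """Aligned behaviour + time series + generating truth, all from one seed."""
    if spec is None:
        spec = bundled_parcellation()
    ss = np.random.SeedSequence(config.seed).spawn(3)
    latents = generate_latents(config, np.random.default_rng(ss[0]))
    behavior = generate_items(latents, config, np.random.default_rng(ss[1]))
    timeseries = generate_timeseries(latents, config, spec)
    truth = CohortTruth(
        es_latent=latents["es_latent"], cr_latent=latents["cr_latent"],
        na_latent=latents["na_latent"], age=latents["age"],
        gender=latents["gender"], config=config,
    )
    return SyntheticCohort(behavior=behavior, timeseries=timeseries, truth=truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the exact input formats the pipeline reads, plus truth.json."""
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for ts in cohort.timeseries:
        rel = f"timeseries/{ts.participant_id}.csv"
        write_timeseries_csv(ts, outdir / rel)
        manifest_rows.append({"participant_id": ts.participant_id, "path": rel})
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    behavior_path = outdir / "behavior.csv"
    write_behavior_csv(cohort.behavior, behavior_path)
    truth_path = outdir / "truth.json"
    t = cohort.truth
    truth_path.write_text(json.dumps({
        "es_latent": t.es_latent.tolist(), "cr_latent": t.cr_latent.tolist(),
        "na_latent": t.na_latent.tolist(), "age": t.age.tolist(),
        "gender": t.gender.tolist(), "config": t.config.to_dict(),
    }, indent=1))
    return {"manifest": manifest_path, "behavior": behavior_path, "truth": truth_path}
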