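"""Group-level threshold screening and per-participant efficiencies.

The screening procedure works on the *group-average* Fisher-z matrix: for
each (network, threshold) cell the average matrix is restricted to the
network's nodes and binarized; the cell passes only if the small-world
property is estimable (mean degree k > log(n)) *and* present (sigma > 1,
strict).  Global efficiency is then computed per participant, but only for
the cells that passed — excluded cells are reported downstream as ``N\\A``.
The inclusion pattern is a property of the cohort's connectivity, so the
expressive-suppression and cognitive-reappraisal report grids share one
``N\\A`` pattern.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import (
    BinaryGraph,
    ConnectivityMatrix,
    average_matrices,
    binarize,
    connection_density,
)
from .errors import UndefinedIndexError, ValidationError
from .graph_metrics import (
    global_efficiency,
    is_estimable,
    mean_degree,
    small_world_indices,
)
from .parcellation import WBN, ParcellationSpec, subnetwork_nodes

log = logging.getLogger(__name__)

#: Number of thresholds in the default sweep.
N_THRESHOLDS = 15


@dataclass(frozen=True)
class ThresholdScreen:
    """Screening verdict for one (network, threshold) cell."""

    network_id: str
    threshold: float
    k_mean: float
    estimable: bool
    sigma: float | None
    included: bool
    density_pct: float


@dataclass(frozen=True)
class NullModelConfig:
    """Degree-preserving null-ensemble settings for sigma."""

    n_random: int = 100
    swaps_per_edge: int = 10


def default_thresholds() -> list[float]:
    """The 15-point Fisher-z threshold sweep: 0.15 to 0.85 in 0.05 steps."""
    return [round(0.15 + 0.05 * i, 2) for i in range(N_THRESHOLDS)]


def screen(
    matrices: Sequence[ConnectivityMatrix],
    spec: ParcellationSpec,
    networks: Sequence[str] | None = None,
    thresholds: Sequence[float] | None = None,
    null_config: NullModelConfig = NullModelConfig(),
    seed: int = 0,
) -> list[ThresholdScreen]:
    """Sweep thresholds on the group-average matrix, one verdict per cell.

    A cell where sigma is undefined against the null ensemble (e.g. a
    saturated complete subgraph whose rewired nulls are identical) is
    recorded as excluded with ``sigma=None`` and a warning rather than
    aborting the sweep.
    """
    if len(matrices) < 2:
        raise ValidationError("screening requires at least 2 participants")
    if networks is None:
        networks = [WBN] + spec.networks
    if thresholds is None:
        thresholds = default_thresholds()
    avg = average_matrices(list(matrices))
    out: list[ThresholdScreen] = []
    for ni, network in enumerate(networks):
        nodes = subnetwork_nodes(spec, network)
        sub = avg.subset(nodes)
        for ti, t in enumerate(thresholds):
            g = binarize(sub, t)
            k = mean_degree(g)
            density = connection_density(g)
            estimable = is_estimable(g)
            sigma = None
            included = False
            if estimable:
                try:
                    sw = small_world_indices(
                        g,
                        n_random=null_config.n_random,
                        swaps_per_edge=null_config.swaps_per_edge,
                        seed=seed + 1000 * ni + 10 * ti,
                    )
                    sigma = sw.sigma
                    included = sigma is not None and sigma > 1.0
                except UndefinedIndexError as exc:
                    warnings.warn(
                        f"sigma undefined for ({network}, {t}): {exc}; cell excluded"
                    )
                    log.warning("sigma undefined for (%s, %s): %s", network, t, exc)
            out.append(
                ThresholdScreen(
                    network_id=network, threshold=float(t), k_mean=k,
                    estimable=estimable, sigma=sigma, included=included,
                    density_pct=density,
                )
            )
    return out


def participant_efficiencies(
    matrices: Sequence[ConnectivityMatrix],
    spec: ParcellationSpec,
    screens: Sequence[ThresholdScreen],
    participant_ids: Sequence[str] | None = None,
    efficiency_definition: str = "mean-inverse",
) -> pd.DataFrame:
    """Long-format efficiency table for every *included* cell.

    Each participant's own Fisher-z matrix is restricted to the network's
    nodes, binarized at the cell's threshold, and scored with global
    efficiency.  Returns columns participant_id, network, threshold, e_glob.
    """
    if participant_ids is None:
        participant_ids = [f"sub-{i + 1:03d}" for i in range(len(matrices))]
    rows = []
    included = [s for s in screens if s.included]
    node_cache: dict[str, list[int]] = {}
    for s in included:
        nodes = node_cache.setdefault(s.network_id, subnetwork_nodes(spec, s.network_id))
        for pid, m in zip(participant_ids, matrices):
            g = binarize(m.subset(nodes), s.threshold)
            rows.append(
                {
                    "participant_id": pid,
                    "network": s.network_id,
                    "threshold": s.threshold,
                    "e_glob": global_efficiency(g, definition=efficiency_definition),
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "network", "threshold", "e_glob"])


def screen_report(screens: Sequence[ThresholdScreen], spec: ParcellationSpec) -> pd.DataFrame:
    """Density grid in the style of a connection-density table.

    Rows are thresholds, columns networks with node counts in the headers;
    excluded cells are printed as ``N\\A``, included ones as density to two
    decimals.
    """
    networks = list(dict.fromkeys(s.network_id for s in screens))
    thresholds = sorted({s.threshold for s in screens})
    cols = {}
    lookup = {(s.network_id, s.threshold): s for s in screens}
    for net in networks:
        size = spec.n_nodes if net == WBN else spec.network_size(net)
        header = f"{net} ({size})"
        col = []
        for t in thresholds:
            s = lookup[(net, t)]
            col.append(f"{s.density_pct:.2f}" if s.included else "N\\A")
        cols[header] = col
    df = pd.DataFrame(cols, index=[f"{t:.2f}" for t in thresholds])
    df.index.name = "threshold"
    return df


def screens_long_table(screens: Sequence[ThresholdScreen]) -> pd.DataFrame:
    """Long-format metric export: one (network, threshold, metric, value) row."""
    rows = []
    for s in screens:
        for metric, value in (
            ("k_mean", s.k_mean), ("estimable", float(s.estimable)),
            ("sigma", np.nan if s.sigma is None else s.sigma),
            ("included", float(s.included)), ("density_pct", s.density_pct),
        ):
            rows.append({"network": s.network_id, "threshold": s.threshold,
                         "metric": metric, "value": value})
    return pd.DataFrame(rows, columns=["network", "threshold", "metric", "value"])


def write_screen_report(screens, spec, path: str | Path) -> None:
    screen_report(screens, spec).to_csv(path, sep="\t")


def write_efficiency_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
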