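"""Fisher-z functional connectivity matrices from regional time series.

Connectivity is estimated as the Pearson correlation between each pair of
regional BOLD time series, variance-stabilized by the Fisher transformation
z = arctanh(r).  Thresholds throughout the pipeline are expressed in Fisher-z
units and an edge requires z strictly above the threshold; negative
correlations therefore never form edges.  Sample correlations are clipped to
+/-(1 - 1e-6) before the transform so perfectly collinear (degenerate
synthetic) inputs stay finite.  Averaging across participants is done on the
Fisher-z matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import AlignmentError, DegenerateInputError, ValidationError

#: Correlations are clipped to +/-(1 - CLIP_EPS) before arctanh.
CLIP_EPS = 1e-6


@dataclass(frozen=True)
class RegionalTimeSeries:
    """T x N matrix of region-averaged BOLD values for one participant."""

    participant_id: str
    values: np.ndarray
    node_ids: tuple[int, ...]
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "node_ids", tuple(int(i) for i in self.node_ids))
        if v.ndim != 2 or v.shape[0] < 3:
            raise ValidationError("time series must be T x N with T >= 3")
        if v.shape[1] != len(self.node_ids):
            raise ValidationError("node_ids length must match number of columns")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("node_ids must be unique")
        if not np.isfinite(v).all():
            raise ValidationError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Fisher-z matrix over an ordered node set; zero diagonal."""

    z: np.ndarray
    node_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "node_ids", tuple(int(i) for i in self.node_ids))
        n = len(self.node_ids)
        if z.shape != (n, n):
            raise ValidationError("z must be N x N matching node_ids")
        if not np.isfinite(z).all():
            raise ValidationError("z contains non-finite entries")
        if not np.allclose(z, z.T, atol=1e-10):
            raise ValidationError("z must be symmetric")
        if not np.allclose(np.diag(z), 0.0):
            raise ValidationError("diagonal must be zero")

    def subset(self, node_ids: Sequence[int]) -> "ConnectivityMatrix":
        """Restrict to the given node ids, in the given order."""
        index = {nid: k for k, nid in enumerate(self.node_ids)}
        try:
            idx = np.array([index[int(i)] for i in node_ids], dtype=int)
        except KeyError as exc:
            raise AlignmentError(f"node id {exc.args[0]} not in matrix") from exc
        return ConnectivityMatrix(self.z[np.ix_(idx, idx)], tuple(int(i) for i in node_ids))


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected self-loop-free adjacency from thresholding a z matrix."""

    adjacency: np.ndarray
    node_ids: tuple[int, ...]
    threshold: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        a = (a != 0).astype(np.int8)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "node_ids", tuple(int(i) for i in self.node_ids))
        n = len(self.node_ids)
        if a.shape != (n, n):
            raise ValidationError("adjacency must be N x N matching node_ids")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValidationError("adjacency must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def fisher_z(r):
    """Fisher transform arctanh(r), clipping |r| to 1 - 1e-6 first.

    Accepts scalars or arrays; odd function; r = 0 maps to 0.
    """
    r = np.asarray(r, dtype=float)
    out = np.arctanh(np.clip(r, -1 + CLIP_EPS, 1 - CLIP_EPS))
    return float(out) if out.ndim == 0 else out


def correlation_matrix(
    ts: RegionalTimeSeries, node_subset: Sequence[int] | None = None
) -> ConnectivityMatrix:
    """Pairwise Pearson correlations of the selected columns, Fisher-transformed.

    Raises :class:`DegenerateInputError` naming the first zero-variance node.
    """
    if node_subset is None:
        node_subset = ts.node_ids
    index = {nid: k for k, nid in enumerate(ts.node_ids)}
    try:
        cols = np.array([index[int(i)] for i in node_subset], dtype=int)
    except KeyError as exc:
        raise AlignmentError(f"node id {exc.args[0]} not in time series") from exc
    x = ts.values[:, cols]
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.asarray(node_subset)[np.argmax(sd == 0)])
        raise DegenerateInputError(
            f"node {bad} has zero-variance time series for participant {ts.participant_id}"
        )
    r = np.corrcoef(x, rowvar=False)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z, tuple(int(i) for i in node_subset))


def average_matrices(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of Fisher-z matrices sharing one node ordering."""
    if not matrices:
        raise ValidationError("average_matrices requires a non-empty list")
    ref = matrices[0].node_ids
    for m in matrices[1:]:
        if m.node_ids != ref:
            raise AlignmentError("connectivity matrices have mismatched node orderings")
    z = np.mean([m.z for m in matrices], axis=0)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, ref)


def binarize(m: ConnectivityMatrix, threshold: float) -> BinaryGraph:
    """Edge (i, j) iff z[i, j] > threshold (strict); threshold must be > 0."""
    if not threshold > 0:
        raise ValidationError("threshold must be positive (Fisher-z units)")
    a = (m.z > threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return BinaryGraph(a, m.node_ids, threshold=float(threshold))


def connection_density(g: BinaryGraph) -> float:
    """Percentage of realized edges out of N(N-1)/2 possible."""
    n = g.n_nodes
    if n < 2:
        raise DegenerateInputError("connection density needs at least 2 nodes")
    return 100.0 * g.n_edges / (n * (n - 1) / 2)


class ConnectivityTransformer(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer: time series -> Fisher-z matrices.

    ``transform`` maps a sequence of :class:`RegionalTimeSeries` to a list of
    :class:`ConnectivityMatrix` (optionally restricted to ``node_subset``).
    """

    def __init__(self, node_subset: Sequence[int] | None = None):
        self.node_subset = node_subset

    def fit(self, X, y=None):  # noqa: D102 - nothing to learn
        return self

    def transform(self, X: Sequence[RegionalTimeSeries]) -> list[ConnectivityMatrix]:
        return [correlation_matrix(ts, self.node_subset) for ts in X]


# --- on-disk formats ------------------------------------------------------

def read_timeseries_csv(path: str | Path, participant_id: str | None = None,
                        tr_seconds: float = 2.0) -> RegionalTimeSeries:
    """One CSV per participant: header row of node ids, T rows of values."""
    path = Path(path)
    df = pd.read_csv(path)
    node_ids = tuple(int(c) for c in df.columns)
    return RegionalTimeSeries(
        participant_id=participant_id or path.stem,
        values=df.to_numpy(dtype=float),
        node_ids=node_ids,
        tr_seconds=tr_seconds,
    )


def write_timeseries_csv(ts: RegionalTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.values, columns=[str(i) for i in ts.node_ids]).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Participant manifest CSV: columns participant_id, path (relative to it)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "path": str})
    for col in ("participant_id", "path"):
        if col not in df.columns:
            raise ValidationError(f"manifest {path} missing column {col!r}")
    df["path"] = [str((path.parent / p).resolve()) for p in df["path"]]
    return df


def write_connectivity_tsv(m: ConnectivityMatrix, path: str | Path) -> None:
    """TSV with node_id header row/column, 6 decimal places."""
    ids = [str(i) for i in m.node_ids]
    pd.DataFrame(m.z, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format="%.6f", index_label="node_id"
    )


def read_connectivity_tsv(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="node_id")
    z = df.to_numpy(dtype=float)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, tuple(int(c) for c in df.columns))
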