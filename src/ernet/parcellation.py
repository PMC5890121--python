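"""Node-to-network assignment for the 264-region brain parcellation.

The whole-brain analyses use a fixed published parcellation of 264 spherical
regions, reduced to 10 named resting-state subnetworks (somato-motor,
cingulo-opercular, auditory, default-mode, visual, fronto-parietal, salience,
subcortical, ventral- and dorsal-attention).  Regions belonging to none of the
10 subnetworks are kept with the label ``Unassigned`` and participate only in
whole-brain-network (WBN) analyses.

The bundled fixture ``data/power264_synthetic_labels.tsv`` carries the
published MNI coordinates of the 264 regions; the node-to-subnetwork *labels*
in that file are a synthetic assignment (the node-level membership list of the
10-network reduction is not republished here) whose per-network counts match
the published ones exactly: SMN 35, CON 14, Aud 13, DMN 58, Vis 31, FPN 25,
SAN 18, Sub 13, VAN 9, DAN 11, Unassigned 37.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

#: Canonical subnetwork sizes of the 10-network reduction of the 264-region
#: parcellation (remaining 37 regions are Unassigned).
CANONICAL_NETWORK_SIZES: Mapping[str, int] = {
    "SMN": 35, "CON": 14, "Aud": 13, "DMN": 58, "Vis": 31,
    "FPN": 25, "SAN": 18, "Sub": 13, "VAN": 9, "DAN": 11,
}

#: Label of the whole-brain network (all nodes, including Unassigned).
WBN = "WBN"

UNASSIGNED = "Unassigned"

_COLUMNS = ["node_id", "x", "y", "z", "network"]


@dataclass(frozen=True)
class ParcellationSpec:
    """A validated node table: id, MNI coordinates (mm), subnetwork label.

    ``expected_sizes`` holds the declared per-network node counts the table
    was validated against (``None`` means sizes were accepted as found --
    used by toy parcellations in tests).
    """

    nodes: pd.DataFrame
    expected_sizes: Mapping[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        df = self.nodes
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"parcellation table missing columns {missing}")
        if df["node_id"].duplicated().any():
            dupes = sorted(df.loc[df["node_id"].duplicated(), "node_id"].tolist())
            raise ValidationError(f"duplicate node_id(s): {dupes}")
        if self.expected_sizes is not None:
            counts = df["network"].value_counts().to_dict()
            for net, size in self.expected_sizes.items():
                if counts.get(net, 0) != size:
                    raise ValidationError(
                        f"subnetwork {net!r} has {counts.get(net, 0)} nodes, expected {size}"
                    )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def networks(self) -> list[str]:
        """Subnetwork labels present, excluding Unassigned, in canonical order."""
        present = set(self.nodes["network"])
        ordered = [n for n in CANONICAL_NETWORK_SIZES if n in present]
        extra = sorted(present - set(ordered) - {UNASSIGNED})
        return ordered + extra

    def network_size(self, network_id: str) -> int:
        return len(subnetwork_nodes(self, network_id))


def load_parcellation(
    path: str | Path,
    expected_sizes: Mapping[str, int] | None = CANONICAL_NETWORK_SIZES,
    expected_total: int | None = 264,
) -> ParcellationSpec:
    """Read a tab-separated node table and validate it.

    The file must have a header ``node_id\\tx\\ty\\tz\\tnetwork`` with integer
    MNI millimetre coordinates.  ``expected_sizes``/``expected_total`` default
    to the canonical 264-node parcellation; pass ``None`` for both to accept a
    toy parcellation as found.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"network": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("node_id", "x", "y", "z"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            line = int(bad.index[0]) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col]).astype(int)
    if expected_total is not None and len(df) != expected_total:
        raise ValidationError(f"{path}: {len(df)} nodes, expected {expected_total}")
    return ParcellationSpec(nodes=df.reset_index(drop=True), expected_sizes=expected_sizes)


def bundled_parcellation() -> ParcellationSpec:
    """The 264-node fixture shipped with the package (synthetic labels)."""
    with resources.as_file(
        resources.files("ernet.data") / "power264_synthetic_labels.tsv"
    ) as p:
        return load_parcellation(p)


def subnetwork_nodes(spec: ParcellationSpec, network_id: str) -> list[int]:
    """Node ids of one subnetwork (ascending), or all nodes for WBN."""
    if network_id == WBN:
        return sorted(spec.nodes["node_id"].tolist())
    known = set(spec.nodes["network"])
    if network_id not in known:
        raise KeyError(f"unknown network label {network_id!r}; known: {sorted(known)} + ['{WBN}']")
    sel = spec.nodes.loc[spec.nodes["network"] == network_id, "node_id"]
    return sorted(sel.tolist())


def write_parcellation(spec: ParcellationSpec, path: str | Path) -> None:
    """Write a spec back to the tab-separated on-disk format (round-trips)."""
    spec.nodes[_COLUMNS].to_csv(path, sep="\t", index=False)
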