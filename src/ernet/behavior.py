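"""Cohort questionnaire table: ERQ items, negative-affect items, demographics.

The behavioural battery is the 10-item Emotion Regulation Questionnaire
(4 expressive-suppression items ``es1..es4`` and 6 cognitive-reappraisal
items ``cr1..cr6``, each on a 1-7 scale) and the 9-item negative-affect
subscale ``na1..na9`` (1-5 scale) whose sum is the NA covariate, plus age in
years and gender coded 0/1 (1 = male).  The cohort is listwise complete: no
missing values are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

ES_ITEMS = [f"es{i}" for i in range(1, 5)]
CR_ITEMS = [f"cr{i}" for i in range(1, 7)]
NA_ITEMS = [f"na{i}" for i in range(1, 10)]
BEHAVIOR_COLUMNS = ["participant_id", *ES_ITEMS, *CR_ITEMS, *NA_ITEMS, "age", "gender"]


@dataclass(frozen=True)
class CohortBehavior:
    """Validated per-participant questionnaire responses."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"behavior table missing columns {missing}")
        if df[BEHAVIOR_COLUMNS].isna().any().any():
            raise ValidationError("behavior table contains missing values")
        for cols, lo, hi in ((ES_ITEMS + CR_ITEMS, 1, 7), (NA_ITEMS, 1, 5)):
            vals = df[cols].to_numpy()
            if ((vals < lo) | (vals > hi)).any():
                raise ValidationError(f"items {cols[0]}.. out of range {lo}..{hi}")
        if not df["gender"].isin([0, 1]).all():
            raise ValidationError("gender must be coded 0/1")

    @property
    def n_participants(self) -> int:
        return len(self.data)

    @property
    def participant_ids(self) -> list[str]:
        return [str(p) for p in self.data["participant_id"]]

    @property
    def na_score(self) -> np.ndarray:
        """Summed negative-affect score per participant (range 9..45)."""
        return self.data[NA_ITEMS].sum(axis=1).to_numpy(dtype=float)

    def sem_frame(self) -> pd.DataFrame:
        """Observed variables the structural model uses (no NA items, NA summed)."""
        out = self.data[["participant_id", *ES_ITEMS, *CR_ITEMS, "age", "gender"]].copy()
        out["na_score"] = self.na_score
        return out


def read_behavior_csv(path: str | Path) -> CohortBehavior:
    return CohortBehavior(pd.read_csv(path, dtype={"participant_id": str}))


def write_behavior_csv(behavior: CohortBehavior, path: str | Path) -> None:
    behavior.data[BEHAVIOR_COLUMNS].to_csv(path, index=False)
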