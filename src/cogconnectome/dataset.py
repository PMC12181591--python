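"""The in-memory cohort container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .roster import Roster, DEFAULT as DEFAULT_ROSTER

#: Demographic columns expected by the eligibility filter and stratification.
DEMOGRAPHIC_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "age",
    "sex",
    "education_level",
    "mmse",
    "bdrs_personality",
    "bdrs_everyday",
    "bdrs_habits",
    "faq",
    "wais_info",
)


@dataclass
class CognitiveDataset:
    """Participants × cognitive-variables table plus demographics.

    Parameters
    ----------
    data
        One row per participant; demographic columns (see
        :data:`DEMOGRAPHIC_COLUMNS`) followed by one column per roster
        variable.
    roster
        Ordered variable roster with module labels and inversion flags.
    z_units
        Whether scores have been converted to cohort z-scores.
    inverted
        Whether the sign inversion of procedural-memory / processing-speed
        variables has been applied.
    """

    data: pd.DataFrame
    roster: Roster = field(default_factory=lambda: DEFAULT_ROSTER)
    z_units: bool = False
    inverted: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in self.roster.names if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset missing roster variables: {missing[:5]}...")
        if "participant_id" not in self.data.columns:
            raise ValueError("dataset missing 'participant_id' column")
        ids = self.data["participant_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate participant ids: {dupes[:10]}")

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> pd.Series:
        return self.data["participant_id"]

    @property
    def scores(self) -> pd.DataFrame:
        """Score matrix (participants × variables) in roster order."""
        return self.data[self.roster.names]

    @property
    def score_matrix(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    def demographics(self, columns: Sequence[str] = DEMOGRAPHIC_COLUMNS) -> pd.DataFrame:
        present = [c for c in columns if c in self.data.columns]
        return self.data[present]

    def subset(self, ids: Sequence) -> "CognitiveDataset":
        """Row subset by participant id, preserving flags."""
        mask = self.data["participant_id"].isin(list(ids))
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    def with_scores(self, scores: pd.DataFrame, **flags) -> "CognitiveDataset":
        data = self.data.copy()
        data[self.roster.names] = scores[self.roster.names].to_numpy()
        return replace(self, data=data, **flags)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        cols = [c for c in DEMOGRAPHIC_COLUMNS if c in self.data.columns]
        cols += [c for c in self.data.columns if c not in cols and c not in self.roster.names]
        cols += self.roster.names
        self.data[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        roster: Roster | None = None,
        z_units: bool = False,
        inverted: bool = False,
    ) -> "CognitiveDataset":
        return cls(
            pd.read_csv(path),
            roster=roster or DEFAULT_ROSTER,
            z_units=z_units,
            inverted=inverted,
        )
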