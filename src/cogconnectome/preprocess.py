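"""Eligibility screening, cohort z-scoring, score inversion, module
composites and the age × reserve stratification.

The screening admits participants with MMSE ≥ 24, FAQ < 6 and BDRS total
< 4, with one exception: a BDRS total ≥ 4 is tolerated when (a) at least
70% of it comes from the "changes in personality, interests and drive"
subscale and (b) the other two subscales are each ≤ 1.5 — such scores
reflect personality change rather than functional impairment.

Optional pre-computed boolean columns (clinical MCI adjudication,
handedness, MRI reading, exclusionary conditions) are AND-ed into the
verdict when present; the pipeline itself makes no clinical judgement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import CognitiveDataset
from .design import (
    AGE_BINS,
    GROUPS,
    Group,
    age_group_of,
)

__all__ = [
    "EligibilityError",
    "GroupStratification",
    "eligibility_filter",
    "zscore_cohort",
    "invert_scores",
    "module_composites",
    "stratify",
]

#: Optional boolean screening columns AND-ed into eligibility when present.
OPTIONAL_SCREEN_COLUMNS: tuple[str, ...] = (
    "mci_free",
    "right_handed",
    "mri_clear",
    "no_exclusionary_condition",
)

_REQUIRED_DEMOGRAPHICS = (
    "mmse",
    "faq",
    "bdrs_personality",
    "bdrs_everyday",
    "bdrs_habits",
)


class EligibilityError(ValueError):
    pass


def eligibility_filter(
    dataset: CognitiveDataset,
) -> tuple[CognitiveDataset, list[tuple[str, str]]]:
    """Apply the screening rules; return (included, excluded-with-reason).

    A participant is included iff MMSE ≥ 24 AND FAQ < 6 AND
    (BDRS total < 4 OR (personality/total ≥ 0.70 AND everyday ≤ 1.5 AND
    habits ≤ 1.5)).  The reason recorded for an exclusion is the first
    failing criterion, checked in the order MMSE, FAQ, BDRS, then any
    optional boolean screen column.
    """
    df = dataset.data
    missing_cols = [c for c in _REQUIRED_DEMOGRAPHICS if c not in df.columns]
    if missing_cols:
        raise EligibilityError(f"missing required demographic fields: {missing_cols}")
    bad = df[list(_REQUIRED_DEMOGRAPHICS)].isna().any(axis=1)
    if bad.any():
        raise EligibilityError(
            "missing demographic values for participants: "
            f"{df.loc[bad, 'participant_id'].tolist()}"
        )

    excluded: list[tuple[str, str]] = []
    keep = np.ones(len(df), dtype=bool)
    optional = [c for c in OPTIONAL_SCREEN_COLUMNS if c in df.columns]
    for idx, row in df.iterrows():
        reason = None
        total = row.bdrs_personality + row.bdrs_everyday + row.bdrs_habits
        if row.mmse < 24:
            reason = "MMSE"
        elif row.faq >= 6:
            reason = "FAQ"
        elif total >= 4:
            fraction = row.bdrs_personality / total
            if not (fraction >= 0.70 and row.bdrs_everyday <= 1.5 and row.bdrs_habits <= 1.5):
                reason = "BDRS"
        if reason is None:
            for col in optional:
                if not bool(row[col]):
                    reason = col
                    break
        if reason is not None:
            keep[df.index.get_loc(idx)] = False
            excluded.append((row.participant_id, reason))

    included = replace(dataset, data=df.loc[keep].reset_index(drop=True))
    return included, excluded


def zscore_cohort(dataset: CognitiveDataset, ddof: int = 1) -> CognitiveDataset:
    """Standardize every variable with whole-cohort mean and SD.

    Uses sample SD (``ddof=1``) by default; pass ``ddof=0`` for the
    population convention (the two differ in the third decimal at cohort
    sizes of a few hundred).  Applying the operation to already
    standardized data is an (approximate) identity.
    """
    scores = dataset.scores.to_numpy(dtype=float)
    sd = scores.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [dataset.roster.names[i] for i in zero]
        raise ValueError(f"zero-variance variables, cannot z-score: {names}")
    z = (scores - scores.mean(axis=0)) / sd
    frame = pd.DataFrame(z, columns=dataset.roster.names, index=dataset.data.index)
    return dataset.with_scores(frame, z_units=True)


def invert_scores(dataset: CognitiveDataset) -> CognitiveDataset:
    """Flip the sign of procedural-memory and processing-speed z-scores so
    that higher z means better performance everywhere.  Involution: applying
    twice restores the input."""
    if not dataset.z_units:
        raise ValueError("invert_scores expects z-scored data")
    frame = dataset.scores.copy()
    inv = dataset.roster.inverted_names
    frame[inv] = -frame[inv]
    return dataset.with_scores(frame, inverted=not dataset.inverted)


def module_composites(dataset: CognitiveDataset) -> pd.DataFrame:
    """Per-participant module performance: mean z-score over the module's
    variables (inversion must already be applied)."""
    if not dataset.z_units or not dataset.inverted:
        raise ValueError("module_composites expects z-scored, inverted data")
    roster = dataset.roster
    out = {}
    for module in roster.modules:
        members = roster.module_members(module)
        if not members:
            raise ValueError(f"module {module} has zero variables")
        out[module] = dataset.scores[members].mean(axis=1)
    frame = pd.DataFrame(out, index=dataset.data.index)
    frame.insert(0, "participant_id", dataset.data["participant_id"])
    return frame


@dataclass
class GroupStratification:
    """Participant → (age_group, reserve_group) assignment."""

    assignments: dict[str, Group]
    split_threshold: float

    def members(self, group: Group) -> list[str]:
        return [pid for pid, g in self.assignments.items() if g == group]

    def counts(self) -> dict[Group, int]:
        return {g: len(self.members(g)) for g in GROUPS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": list(self.assignments),
                "age_group": [g[0] for g in self.assignments.values()],
                "reserve_group": [g[1] for g in self.assignments.values()],
            }
        )


def stratify(
    dataset: CognitiveDataset, threshold: float | None = None
) -> GroupStratification:
    """Assign each participant to one of the six age × reserve cells.

    Age bins are the closed integer intervals 37–50 / 51–64 / 65–78
    (non-integer ages are floored).  Reserve is high when the WAIS-III
    Information score exceeds ``threshold``, low otherwise; the default
    threshold is the cohort median.
    """
    df = dataset.data
    ages = df["age"].to_numpy()
    floored = np.floor(ages).astype(int)
    out_of_range = (floored < AGE_BINS["EMA"][0]) | (floored > AGE_BINS["ELD"][1])
    if out_of_range.any():
        ids = df.loc[out_of_range, "participant_id"].tolist()
        raise ValueError(f"ages outside 37-78 for participants: {ids}")
    if threshold is None:
        threshold = float(np.median(df["wais_info"].to_numpy()))
    assignments: dict[str, Group] = {}
    for pid, age, wais in zip(df["participant_id"], floored, df["wais_info"]):
        reserve = "high" if wais > threshold else "low"
        assignments[pid] = (age_group_of(age), reserve)
    return GroupStratification(assignments=assignments, split_threshold=float(threshold))


def preprocess_pipeline(
    dataset: CognitiveDataset,
    ddof: int = 1,
    threshold: float | None = None,
) -> tuple[CognitiveDataset, GroupStratification, list[tuple[str, str]]]:
    """Screen, z-score, invert and stratify in the canonical order."""
    included, excluded = eligibility_filter(dataset)
    z = invert_scores(zscore_cohort(included, ddof=ddof))
    strat = stratify(z, threshold=threshold)
    return z, strat, excluded


def group_score_matrix(
    dataset: CognitiveDataset, strat: GroupStratification, group: Group
) -> np.ndarray:
    """Score matrix (participants × variables) of one stratification cell."""
    ids = set(strat.members(group))
    mask = dataset.data["participant_id"].isin(ids).to_numpy()
    return dataset.score_matrix[mask]
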