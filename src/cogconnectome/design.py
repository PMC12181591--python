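"""Study design constants: age bins, reserve levels, the 3 × 2 group grid.

Age groups
    ``EMA`` early middle age, 37–50 years; ``LMA`` late middle age,
    51–64 years; ``ELD`` elderly, 65–78 years (closed integer intervals).

Cognitive reserve
    Proxied by the WAIS-III Information raw score; a median split assigns
    ``high`` (score > threshold) vs ``low`` (score ≤ threshold), with 15 the
    reference cohort's median.
"""

from __future__ import annotations

AGE_GROUPS: tuple[str, ...] = ("EMA", "LMA", "ELD")
RESERVE_GROUPS: tuple[str, ...] = ("high", "low")

#: Closed integer age intervals per age group.
AGE_BINS: dict[str, tuple[int, int]] = {
    "EMA": (37, 50),
    "LMA": (51, 64),
    "ELD": (65, 78),
}

#: WAIS-III Information median split used in the reference cohort.
DEFAULT_RESERVE_THRESHOLD: int = 15

Group = tuple[str, str]  # (age_group, reserve_group)

#: Canonical ordering of the six cells.
GROUPS: tuple[Group, ...] = tuple(
    (a, r) for r in RESERVE_GROUPS for a in AGE_GROUPS
)

#: Cell sizes of the reference ageing cohort (sums to 334).
DEFAULT_GROUP_SIZES: dict[Group, int] = {
    ("EMA", "high"): 59,
    ("LMA", "high"): 67,
    ("ELD", "high"): 40,
    ("EMA", "low"): 51,
    ("LMA", "low"): 39,
    ("ELD", "low"): 78,
}

#: The nine default group contrasts: age effects within each reserve level,
#: then reserve effects within each age group.
DEFAULT_COMPARISONS: tuple[tuple[Group, Group], ...] = (
    (("EMA", "high"), ("LMA", "high")),
    (("LMA", "high"), ("ELD", "high")),
    (("EMA", "high"), ("ELD", "high")),
    (("EMA", "low"), ("LMA", "low")),
    (("LMA", "low"), ("ELD", "low")),
    (("EMA", "low"), ("ELD", "low")),
    (("EMA", "high"), ("EMA", "low")),
    (("LMA", "high"), ("LMA", "low")),
    (("ELD", "high"), ("ELD", "low")),
)


def group_label(group: Group) -> str:
    """Human-readable label, e.g. ``'EMA-high'``."""
    return f"{group[0]}-{group[1]}"


def age_group_of(age: float) -> str:
    """Assign an age (years) to its bin; ages are floored to integers."""
    a = int(age)
    for name, (lo, hi) in AGE_BINS.items():
        if lo <= a <= hi:
            return name
    raise ValueError(f"age {age} outside the supported range 37-78")
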