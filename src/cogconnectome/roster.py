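"""Variable roster for the cognitive test battery.

The default roster lists the 47 cognitive variables of the battery, each
allocated to one of five cognitive modules:

* ``VM``  — verbal memory
* ``VMV`` — visual memory and visuospatial functions
* ``EPF`` — executive and premotor functions
* ``PM``  — procedural memory
* ``PS``  — processing speed

Variables in the procedural-memory and processing-speed modules are scored
so that *lower* raw values mean better performance (timings, error counts);
their ``inverted`` flag marks them for sign inversion after z-scoring so
that higher z always denotes better performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

MODULES: tuple[str, ...] = ("VM", "VMV", "EPF", "PM", "PS")

MODULE_NAMES: Mapping[str, str] = {
    "VM": "verbal memory",
    "VMV": "visual memory and visuospatial functions",
    "EPF": "executive and premotor functions",
    "PM": "procedural memory",
    "PS": "processing speed",
}

#: Modules whose variables are inverted after z-scoring.
INVERTED_MODULES: frozenset[str] = frozenset({"PM", "PS"})


@dataclass(frozen=True)
class Variable:
    """One cognitive variable: column name, module code, inversion flag."""

    name: str
    module: str
    inverted: bool

    def __post_init__(self) -> None:
        if self.module not in MODULES:
            raise ValueError(f"unknown module {self.module!r} for variable {self.name!r}")


def _vars(module: str, names: Iterable[str]) -> list[Variable]:
    inv = module in INVERTED_MODULES
    return [Variable(n, module, inv) for n in names]


# Logical Memory (LM), TAVEC (Spanish verbal learning test) -> verbal memory;
# FRT, JLOT, spatial span backward, Visual Reproduction, block design, BNT and
# the 8/30 Spatial Recall Test (SRT) -> visual memory / visuospatial; Stroop,
# fluencies, spans, hand-alternating movements -> executive & premotor;
# Hanoi Tower -> procedural memory; PC-Vienna and Color Trails -> speed.
DEFAULT_ROSTER: tuple[Variable, ...] = tuple(
    _vars(
        "VM",
        [
            "lm_a_immediate",
            "lm_b1_immediate",
            "lm_b2_immediate",
            "lm_a_delayed",
            "lm_b_delayed",
            "lm_a_recognition",
            "lm_b_recognition",
            "tavec_1st_trial",
            "tavec_learning",
            "tavec_interference",
            "tavec_immediate_total",
            "tavec_cued_immediate_recall",
            "tavec_delayed_total",
            "tavec_cued_delayed_recall",
        ],
    )
    + _vars(
        "VMV",
        [
            "frt",
            "jlot_1st_half",
            "jlot_2nd_half",
            "spatial_span_backward",
            "vr_i_total",
            "vr_ii_total",
            "vr_copy",
            "vr_recognition",
            "block_design_total",
            "bnt",
            "srt_1st_trial",
            "srt_learning",
            "srt_interference",
            "srt_immediate",
            "srt_delayed",
        ],
    )
    + _vars(
        "EPF",
        [
            "stroop_words",
            "stroop_colours",
            "stroop_inhibition",
            "phonetic_fluency",
            "semantic_fluency",
            "action_fluency",
            "digit_span_forward",
            "digit_span_backward",
            "spatial_span_forward",
            "ham_right",
            "ham_left",
            "ham_motor_coordination",
        ],
    )
    + _vars("PM", ["ht_1st_trial", "ht_learning", "ht_long_delay"])
    + _vars("PS", ["pcv_decision_time", "pcv_motor_time", "ctt_part_a"])
)


class Roster:
    """Ordered collection of :class:`Variable` with module/inversion lookups."""

    def __init__(self, variables: Iterable[Variable] = DEFAULT_ROSTER):
        self.variables: tuple[Variable, ...] = tuple(variables)
        self._validate()

    def _validate(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in roster")
        present = {v.module for v in self.variables}
        missing = [m for m in MODULES if m not in present]
        if missing:
            raise ValueError(f"modules with zero variables: {missing}")
        bad = [v.name for v in self.variables if v.inverted != (v.module in INVERTED_MODULES)]
        if bad:
            raise ValueError(
                "inversion flags must mark exactly the procedural-memory and "
                f"processing-speed variables; inconsistent: {bad}"
            )

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def module_map(self) -> dict[str, str]:
        return {v.name: v.module for v in self.variables}

    @property
    def inverted_names(self) -> list[str]:
        return [v.name for v in self.variables if v.inverted]

    def module_members(self, module: str) -> list[str]:
        return [v.name for v in self.variables if v.module == module]

    @property
    def modules(self) -> tuple[str, ...]:
        seen: list[str] = []
        for v in self.variables:
            if v.module not in seen:
                seen.append(v.module)
        return tuple(seen)

    # -- sidecar I/O -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.names,
                "module": [v.module for v in self.variables],
                "inverted": [v.inverted for v in self.variables],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        records = [
            {"variable": v.name, "module": v.module, "inverted": v.inverted}
            for v in self.variables
        ]
        Path(path).write_text(json.dumps(records, indent=2))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Roster":
        return cls(
            Variable(str(r.variable), str(r.module), bool(r.inverted))
            for r in frame.itertuples(index=False)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Roster":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def from_json(cls, path: str | Path) -> "Roster":
        records = json.loads(Path(path).read_text())
        return cls(Variable(r["variable"], r["module"], bool(r["inverted"])) for r in records)


DEFAULT = Roster()
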