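"""Cohort-level statistics: age × reserve MANOVA on the five module
composites, follow-up per-module ANOVAs, and descriptive tables.

The MANOVA enters age group (3 levels) and cognitive reserve (2 levels) as
between-subject factors, with the five module composites as responses, and
reports Wilks' Λ for the interaction with Rao's F approximation (numerator
df = 5 responses × 2 interaction df).  Canonical discriminant functions of
the interaction come from the generalized eigenproblem H v = λ E v, with
the first function's sign fixed so that positive values mean higher overall
cognitive performance.  Follow-up ANOVAs use type-II sums of squares (for
the highest-order interaction term this coincides with type III, so the
unbalanced cells are handled consistently).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.anova import anova_lm

from .dataset import CognitiveDataset
from .design import GROUPS, group_label
from .preprocess import GroupStratification
from .roster import MODULES

__all__ = [
    "ManovaResult",
    "manova_interaction",
    "manova_sex_sensitivity",
    "followup_anovas",
    "descriptives",
]


@dataclass
class ManovaResult:
    """Wilks' Λ test of one model term plus canonical structure."""

    term: str
    wilks_lambda: float
    f_stat: float
    df: tuple[float, float]
    p_value: float
    canonical_group_means: pd.DataFrame | None = None
    structure_coefficients: pd.DataFrame | None = None
    eigenvalues: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.wilks_lambda <= 1 + 1e-9):
            raise ValueError(f"Wilks lambda {self.wilks_lambda} outside (0, 1]")


def _interaction_frame(
    composites: pd.DataFrame, age_group: pd.Series, reserve_group: pd.Series,
    sex: pd.Series | None = None, responses: tuple[str, ...] = MODULES,
) -> pd.DataFrame:
    frame = composites[list(responses)].copy()
    frame["age_group"] = np.asarray(age_group, dtype=object)
    frame["reserve_group"] = np.asarray(reserve_group, dtype=object)
    if sex is not None:
        frame["sex"] = np.asarray(sex, dtype=object)
    counts = frame.groupby(["age_group", "reserve_group"], observed=True).size()
    if len(counts) < 6 or (counts < 2).any():
        raise ValueError("all six age x reserve cells need >= 2 participants")
    return frame.reset_index(drop=True)


def _extract_wilks(mv_results: dict, term: str) -> tuple[float, float, tuple, float]:
    stat = mv_results[term]["stat"]
    row = stat.loc["Wilks' lambda"]
    return (
        float(row["Value"]),
        float(row["F Value"]),
        (float(row["Num DF"]), float(row["Den DF"])),
        float(row["Pr > F"]),
    )


def manova_interaction(
    composites: pd.DataFrame,
    age_group: pd.Series,
    reserve_group: pd.Series,
    responses: tuple[str, ...] = MODULES,
) -> ManovaResult:
    """Wilks' Λ for the age × reserve interaction on the module composites,
    with canonical discriminant functions of the interaction effect."""
    frame = _interaction_frame(composites, age_group, reserve_group,
                               responses=responses)
    if len(responses) == 1:
        # degenerate single-response case: Wilks reduces to the exact
        # univariate interaction F with Lambda = SSE/(SSE + SSH)
        fit = smf.ols(
            f"{responses[0]} ~ C(age_group)*C(reserve_group)", data=frame
        ).fit()
        table = anova_lm(fit, typ=2)
        inter = table.loc["C(age_group):C(reserve_group)"]
        df_num = float(inter["df"])
        df_den = float(table.loc["Residual", "df"])
        f_stat = float(inter["F"])
        wilks = 1.0 / (1.0 + f_stat * df_num / df_den)
        return ManovaResult(
            term="age_group:reserve_group",
            wilks_lambda=wilks,
            f_stat=f_stat,
            df=(df_num, df_den),
            p_value=float(inter["PR(>F)"]),
            metadata={"n": len(frame)},
        )
    formula = " + ".join(responses) + " ~ C(age_group)*C(reserve_group)"
    mv = MANOVA.from_formula(formula, data=frame).mv_test()
    term = "C(age_group):C(reserve_group)"
    wilks, f_stat, df, p = _extract_wilks(mv.results, term)

    h = np.asarray(mv.results[term]["H"], dtype=float)
    e = np.asarray(mv.results[term]["E"], dtype=float)
    # canonical discriminant functions: H v = lambda E v
    eigvals, eigvecs = scipy.linalg.eigh(h, e)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_funcs = min(len(responses), 2)
    y = frame[list(responses)].to_numpy()
    scores = (y - y.mean(axis=0)) @ eigvecs[:, :n_funcs]
    # orient function 1 so that positive = better overall performance
    overall = y.mean(axis=1)
    for j in range(n_funcs):
        r = np.corrcoef(scores[:, j], overall)[0, 1]
        if r < 0:
            scores[:, j] *= -1
            eigvecs[:, j] *= -1
    labels = [f"canonical_{j + 1}" for j in range(n_funcs)]
    score_frame = pd.DataFrame(scores, columns=labels)
    score_frame["group"] = [
        group_label((a, r))
        for a, r in zip(frame["age_group"], frame["reserve_group"])
    ]
    group_means = score_frame.groupby("group").mean()
    structure = pd.DataFrame(
        {
            lab: [float(np.corrcoef(y[:, i], scores[:, j])[0, 1])
                  for i in range(len(responses))]
            for j, lab in enumerate(labels)
        },
        index=list(responses),
    )
    return ManovaResult(
        term="age_group:reserve_group",
        wilks_lambda=wilks,
        f_stat=f_stat,
        df=df,
        p_value=p,
        canonical_group_means=group_means,
        structure_coefficients=structure,
        eigenvalues=eigvals,
        metadata={"n": len(frame), "H": h, "E": e},
    )


def manova_sex_sensitivity(
    composites: pd.DataFrame,
    age_group: pd.Series,
    reserve_group: pd.Series,
    sex: pd.Series,
) -> ManovaResult:
    """Three-way age × reserve × sex interaction (sensitivity analysis)."""
    frame = _interaction_frame(composites, age_group, reserve_group, sex=sex)
    formula = " + ".join(MODULES) + " ~ C(age_group)*C(reserve_group)*C(sex)"
    mv = MANOVA.from_formula(formula, data=frame).mv_test()
    term = "C(age_group):C(reserve_group):C(sex)"
    wilks, f_stat, df, p = _extract_wilks(mv.results, term)
    return ManovaResult(
        term="age_group:reserve_group:sex",
        wilks_lambda=wilks, f_stat=f_stat, df=df, p_value=p,
        metadata={"n": len(frame)},
    )


def followup_anovas(
    composites: pd.DataFrame,
    age_group: pd.Series,
    reserve_group: pd.Series,
    ss_type: int = 2,
) -> pd.DataFrame:
    """Interaction F and p per module composite (two-way ANOVA)."""
    frame = _interaction_frame(composites, age_group, reserve_group)
    rows = []
    for module in MODULES:
        fit = smf.ols(f"{module} ~ C(age_group)*C(reserve_group)", data=frame).fit()
        table = anova_lm(fit, typ=ss_type)
        inter = table.loc["C(age_group):C(reserve_group)"]
        rows.append(
            {
                "module": module,
                "F": float(inter["F"]),
                "p": float(inter["PR(>F)"]),
                "df_num": float(inter["df"]),
                "df_den": float(table.loc["Residual", "df"]),
            }
        )
    return pd.DataFrame(rows)


def descriptives(
    dataset: CognitiveDataset,
    stratification: GroupStratification,
    composites: pd.DataFrame | None = None,
) -> dict:
    """Per-cell cohort characteristics plus the standard association checks.

    Returns a dict with a per-group summary table (n, % women, mean (SD) of
    age, MMSE, WAIS and each module composite), Spearman correlations of
    MMSE with age and of education with WAIS, and a χ² test (no continuity
    correction) of sex distribution across the six groups.
    """
    df = dataset.data.set_index("participant_id")
    strat = stratification.to_frame().set_index("participant_id")
    merged = df.join(strat, how="inner")
    if composites is not None:
        merged = merged.join(
            composites.set_index("participant_id")[list(MODULES)], how="left"
        )
    rows = []
    for group in GROUPS:
        cell = merged[
            (merged["age_group"] == group[0]) & (merged["reserve_group"] == group[1])
        ]
        row: dict = {"group": group_label(group), "n": len(cell)}
        if len(cell):
            women = (cell["sex"] == "F").sum()
            row["n_women"] = int(women)
            row["pct_women"] = 100.0 * women / len(cell)
            for col in ("age", "mmse", "wais_info") + tuple(
                m for m in MODULES if m in cell.columns
            ):
                row[f"{col}_mean"] = float(cell[col].mean())
                row[f"{col}_sd"] = float(cell[col].std(ddof=1)) if len(cell) > 1 else 0.0
        rows.append(row)
    table = pd.DataFrame(rows)

    rho_mmse, p_mmse = scipy.stats.spearmanr(merged["mmse"], merged["age"])
    rho_edu, p_edu = scipy.stats.spearmanr(
        merged["education_level"], merged["wais_info"]
    )
    contingency = pd.crosstab(
        merged["sex"], merged["age_group"] + "-" + merged["reserve_group"]
    )
    chi2, p_chi2, dof, _ = scipy.stats.chi2_contingency(
        contingency.to_numpy(), correction=False
    )
    return {
        "table": table,
        "spearman": {
            "mmse_age": {"rho": float(rho_mmse), "p": float(p_mmse)},
            "education_wais": {"rho": float(rho_edu), "p": float(p_edu)},
        },
        "chi2_sex": {"chi2": float(chi2), "p": float(p_chi2), "dof": int(dof)},
    }
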