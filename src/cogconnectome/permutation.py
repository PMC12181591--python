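"""Permutation comparison of global network measures between two groups.

Because a cognitive connectome is a *group-level* object, the only
exchangeable unit under the null hypothesis of no group difference is the
participant: each permutation pools the two groups' rows, re-splits them at
the original group sizes, rebuilds both connectomes and recomputes the
measure at every density of the grid.  Two-tailed p-values use the
add-one convention p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (1 + n_perm), which can
never return 0.

A density-resolved measure counts as a *stable* group difference only when
p < α at a minimum number of grid densities (default 10 of the 41), which
guards against isolated threshold artefacts.  Strength is density-free and
gets a single p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .connectome import density_grid
from .dataset import CognitiveDataset
from .design import DEFAULT_COMPARISONS, Group, group_label
from .measures import MEASURES, modularity, small_worldness
from .preprocess import GroupStratification, group_score_matrix

__all__ = [
    "PermutationComparison",
    "permutation_test",
    "stability_filter",
    "run_design",
    "comparisons_to_frame",
    "summary_dict",
]

#: Published permutation counts: 1000, but 100 for the costly σ measure.
DEFAULT_N_PERM: dict[str, int] = {m: 1000 for m in MEASURES}
DEFAULT_N_PERM["small_worldness"] = 100

#: Reduced randomization ensemble for σ inside permutation loops.
DEFAULT_SW_ENSEMBLE_PERM = 10

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_DENSITIES = 10


def _connectome_edges(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(ranked edge arrays, weights, mean nodal strength) of a z-matrix."""
    r = np.corrcoef(x, rowvar=False)
    w = np.clip(r, 0.0, None)
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, 1)
    wv = w[iu, ju]
    pos = wv > 0
    iu, ju, wv = iu[pos], ju[pos], wv[pos]
    order = np.lexsort((ju, iu, -wv))
    strength = float(w.sum(axis=1).mean())
    return iu[order].astype(np.int32), ju[order].astype(np.int32), wv[order], strength


def _measure_values(
    x: np.ndarray,
    densities: np.ndarray,
    measure: str,
    sw_ensemble: int,
    rng: np.random.Generator,
) -> np.ndarray | float:
    """Measure curve (or strength scalar) for one group's z-matrix."""
    ei, ej, _, strength = _connectome_edges(x)
    if measure == "strength":
        return strength
    n = x.shape[1]
    n_pairs = n * (n - 1) // 2
    ks = np.minimum(
        np.floor(densities * n_pairs + 0.5).astype(np.int64), ei.size
    )
    if measure == "global_efficiency":
        curve_fn = (
            _kernels.efficiency_curve_bits if n <= 64 else _kernels.efficiency_curve
        )
        return np.asarray(curve_fn(ei, ej, ks, n))
    out = np.empty(len(densities))
    adj = np.zeros((n, n), dtype=bool)
    prev = 0
    for idx, k in enumerate(ks):
        adj[ei[prev:k], ej[prev:k]] = True
        adj[ej[prev:k], ei[prev:k]] = True
        prev = int(k)
        if measure == "local_efficiency":
            out[idx] = _kernels.local_efficiency(adj, n)
        elif measure == "modularity":
            out[idx] = modularity(adj)[0]
        elif measure == "small_worldness":
            out[idx] = small_worldness(
                adj, ensemble_size=sw_ensemble, seed=int(rng.integers(2**31))
            )
        else:
            raise ValueError(f"unknown measure {measure!r}")
    return out


@dataclass
class PermutationComparison:
    """Result of one group-pair comparison for one measure."""

    group_pair: tuple[Group, Group]
    measure_name: str
    observed_diff: Mapping[float, float] | float  # A - B
    p_values: Mapping[float, float] | float
    n_perm: int
    seed: int
    significant_densities: int
    stable_significant: bool
    alpha: float = DEFAULT_ALPHA
    min_densities: int = DEFAULT_MIN_DENSITIES
    null_quantiles: Mapping[float, tuple[float, float]] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def is_scalar(self) -> bool:
        return np.isscalar(self.p_values)

    def to_frame(self) -> pd.DataFrame:
        a, b = (group_label(g) for g in self.group_pair)
        if self.is_scalar:
            rows = [
                {"group_a": a, "group_b": b, "measure": self.measure_name,
                 "density": np.nan, "obs_diff": float(self.observed_diff),
                 "p": float(self.p_values)}
            ]
        else:
            rows = [
                {"group_a": a, "group_b": b, "measure": self.measure_name,
                 "density": d, "obs_diff": self.observed_diff[d],
                 "p": self.p_values[d]}
                for d in self.p_values
            ]
        return pd.DataFrame(rows)


def stability_filter(
    p_values: Mapping[float, float] | Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    min_densities: int = DEFAULT_MIN_DENSITIES,
) -> tuple[int, bool]:
    """Count densities with p < alpha; stable iff the count reaches
    ``min_densities``."""
    vals = np.asarray(
        list(p_values.values()) if isinstance(p_values, Mapping) else list(p_values),
        dtype=float,
    )
    count = int(np.count_nonzero(vals < alpha))
    return count, count >= min_densities


def permutation_test(
    data_a: np.ndarray,
    data_b: np.ndarray,
    measure: str = "global_efficiency",
    densities: np.ndarray | None = None,
    n_perm: int | None = None,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    min_densities: int = DEFAULT_MIN_DENSITIES,
    sw_ensemble: int = DEFAULT_SW_ENSEMBLE_PERM,
    group_pair: tuple[Group, Group] | None = None,
    keep_null_quantiles: bool = False,
) -> PermutationComparison:
    """Two-tailed permutation test of one measure between two groups.

    ``data_a`` and ``data_b`` are z-score matrices (participants ×
    variables, inversion applied) on a common roster.
    """
    a = np.asarray(data_a, float)
    b = np.asarray(data_b, float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the variable roster")
    if a.shape[0] < 4 or b.shape[0] < 4:
        raise ValueError("each group needs at least 4 participants")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if densities is None:
        densities = density_grid()
    if n_perm is None:
        n_perm = DEFAULT_N_PERM[measure]

    rng = np.random.default_rng(seed)
    obs_a = _measure_values(a, densities, measure, sw_ensemble, rng)
    obs_b = _measure_values(b, densities, measure, sw_ensemble, rng)
    obs = np.atleast_1d(np.asarray(obs_a) - np.asarray(obs_b))
    obs_abs = np.abs(obs)

    pooled = np.vstack([a, b])
    # canonical row order and split sizes: the null draws then depend only
    # on the pooled sample, so swapping the group labels negates the
    # observed difference but leaves the p-values exactly unchanged
    pooled = pooled[np.lexsort(pooled.T[::-1])]
    n_first, n_tot = min(a.shape[0], b.shape[0]), pooled.shape[0]
    exceed = np.zeros_like(obs_abs, dtype=np.int64)
    null: list[np.ndarray] = []
    for _ in range(n_perm):
        idx = rng.permutation(n_tot)
        pa = _measure_values(pooled[idx[:n_first]], densities, measure, sw_ensemble, rng)
        pb = _measure_values(pooled[idx[n_first:]], densities, measure, sw_ensemble, rng)
        diff = np.atleast_1d(np.asarray(pa) - np.asarray(pb))
        exceed += np.abs(diff) >= obs_abs
        if keep_null_quantiles:
            null.append(diff)
    p = (1 + exceed) / (1 + n_perm)

    scalar = measure == "strength"
    quantiles = None
    if keep_null_quantiles and null:
        arr = np.vstack(null)
        lo = np.percentile(arr, 2.5, axis=0)
        hi = np.percentile(arr, 97.5, axis=0)
        if not scalar:
            quantiles = {
                float(d): (float(l), float(h))
                for d, l, h in zip(densities, lo, hi)
            }
        else:
            quantiles = {0.0: (float(lo[0]), float(hi[0]))}
    if scalar:
        sig = int(p[0] < alpha)
        stable = bool(p[0] < alpha)
        observed: Mapping[float, float] | float = float(obs[0])
        pvals: Mapping[float, float] | float = float(p[0])
    else:
        sig, stable = stability_filter(dict(zip(densities, p)), alpha, min_densities)
        observed = {float(d): float(v) for d, v in zip(densities, obs)}
        pvals = {float(d): float(v) for d, v in zip(densities, p)}
    return PermutationComparison(
        group_pair=group_pair or (("?", "?"), ("?", "?")),
        measure_name=measure,
        observed_diff=observed,
        p_values=pvals,
        n_perm=n_perm,
        seed=seed,
        significant_densities=sig,
        stable_significant=stable,
        alpha=alpha,
        min_densities=min_densities,
        null_quantiles=quantiles,
        metadata={"sw_ensemble": sw_ensemble} if measure == "small_worldness" else {},
    )


def derive_seed(master_seed: int, comparison_index: int, measure_index: int) -> int:
    """Stable per-test seed: SeedSequence keyed by (comparison, measure), so
    adding comparisons or measures never shifts existing seeds."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(comparison_index, measure_index))
    return int(ss.generate_state(1)[0] % 2**31)


def run_design(
    dataset: CognitiveDataset,
    stratification: GroupStratification,
    design: Sequence[tuple[Group, Group]] | None = None,
    measures: Sequence[str] = MEASURES,
    master_seed: int = 0,
    n_perm: Mapping[str, int] | int | None = None,
    densities: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_densities: int = DEFAULT_MIN_DENSITIES,
    sw_ensemble: int = DEFAULT_SW_ENSEMBLE_PERM,
    keep_null_quantiles: bool = False,
) -> list[PermutationComparison]:
    """All group-pair × measure permutation comparisons of the study design.

    The default design holds the nine contrasts: the three age contrasts
    within each reserve level and the reserve contrast within each age
    group.
    """
    if design is None:
        design = DEFAULT_COMPARISONS
    if not dataset.z_units or not dataset.inverted:
        raise ValueError("run_design expects z-scored, inversion-applied data")
    matrices: dict[Group, np.ndarray] = {}
    for pair in design:
        for g in pair:
            if g not in matrices:
                m = group_score_matrix(dataset, stratification, g)
                if m.shape[0] == 0:
                    raise ValueError(f"empty stratification cell {group_label(g)}")
                matrices[g] = m
    results = []
    for ci, pair in enumerate(design):
        for mi, measure in enumerate(measures):
            if isinstance(n_perm, Mapping):
                np_i = n_perm.get(measure, DEFAULT_N_PERM[measure])
            else:
                np_i = n_perm
            results.append(
                permutation_test(
                    matrices[pair[0]],
                    matrices[pair[1]],
                    measure=measure,
                    densities=densities,
                    n_perm=np_i,
                    seed=derive_seed(master_seed, ci, mi),
                    alpha=alpha,
                    min_densities=min_densities,
                    sw_ensemble=sw_ensemble,
                    group_pair=pair,
                    keep_null_quantiles=keep_null_quantiles,
                )
            )
    return results


def comparisons_to_frame(results: Sequence[PermutationComparison]) -> pd.DataFrame:
    """Tidy (pair, measure, density, obs_diff, p) table."""
    return pd.concat([r.to_frame() for r in results], ignore_index=True)


def summary_dict(results: Sequence[PermutationComparison]) -> dict:
    """JSON-ready verdict summary."""
    return {
        "n_comparisons": len(results),
        "results": [
            {
                "group_a": group_label(r.group_pair[0]),
                "group_b": group_label(r.group_pair[1]),
                "measure": r.measure_name,
                "n_perm": r.n_perm,
                "significant_densities": r.significant_densities,
                "stable_significant": bool(r.stable_significant),
            }
            for r in results
        ],
    }


def write_summary(results: Sequence[PermutationComparison], path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary_dict(results), indent=2))
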