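"""Global graph measures of the cognitive connectome.

Five measures characterize each group network: *network strength*
(centrality; mean nodal sum of correlation weights, computed on the
weighted matrix), *global efficiency* (integration; mean inverse shortest
path over all ordered node pairs, unreachable pairs contributing zero),
*local efficiency* (segregation; mean over nodes of the global efficiency
of the neighbour-induced subgraph), *modularity* (quality Q of the
partition found by Newman's spectral leading-eigenvector algorithm with
Kernighan–Lin-style refinement), and *small-worldness*
σ = (C/C_rand)/(L/L_rand), where the reference values are means over an
ensemble of degree-preserving edge-swap randomizations.

All binary measures operate on the thresholded graphs of the density sweep;
strength is the only weighted (density-free) measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numba import njit

from . import _kernels
from .connectome import WeightedConnectome, BinaryGraphStack, build_stack

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURES",
    "MeasureCurve",
    "UndefinedMeasureError",
    "network_strength",
    "global_efficiency",
    "local_efficiency",
    "clustering_and_pathlength",
    "modularity_q",
    "modularity",
    "small_worldness",
    "compute_measures",
]

MEASURES: tuple[str, ...] = (
    "strength",
    "global_efficiency",
    "local_efficiency",
    "modularity",
    "small_worldness",
)

#: Measures evaluated on binarized graphs across the density grid.
DENSITY_MEASURES: tuple[str, ...] = MEASURES[1:]


class UndefinedMeasureError(ValueError):
    """A measure is undefined on the given graph (e.g. no edges)."""


def _as_adjacency(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.dtype != bool:
        a = a != 0
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a)):
        raise ValueError("adjacency must have zero diagonal")
    return np.ascontiguousarray(a)


# ---------------------------------------------------------------------------
# weighted measure
# ---------------------------------------------------------------------------

def network_strength(conn: WeightedConnectome | np.ndarray) -> float:
    """Mean over nodes of the nodal strength (sum of edge weights)."""
    w = conn.weights if isinstance(conn, WeightedConnectome) else np.asarray(conn, float)
    return float(w.sum(axis=1).mean())


# ---------------------------------------------------------------------------
# binary measures
# ---------------------------------------------------------------------------

def global_efficiency(adj: np.ndarray) -> float:
    """Mean of 1/d over ordered node pairs; unreachable pairs contribute 0."""
    a = _as_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        return 0.0
    inv_sum, _, _ = _kernels.distance_stats(a, n)
    return float(inv_sum / (n * (n - 1)))


def local_efficiency(adj: np.ndarray) -> float:
    """Mean over nodes of the neighbour-subgraph global efficiency."""
    a = _as_adjacency(adj)
    return float(_kernels.local_efficiency(a, a.shape[0]))


def clustering_and_pathlength(adj: np.ndarray) -> tuple[float, float]:
    """(mean clustering coefficient, characteristic path length).

    L averages shortest-path lengths over connected ordered pairs only;
    the number of excluded (unreachable) pairs is logged.
    """
    a = _as_adjacency(adj)
    n = a.shape[0]
    c = float(_kernels.clustering_coefficient(a, n))
    _, d_sum, reach = _kernels.distance_stats(a, n)
    if reach == 0:
        raise UndefinedMeasureError("path length undefined: no connected node pair")
    excluded = n * (n - 1) - reach
    if excluded:
        logger.debug("path length computed over %d pairs (%d unreachable excluded)",
                     reach, excluded)
    return c, float(d_sum / reach)


def modularity_q(adj: np.ndarray, membership: np.ndarray) -> float:
    """Newman–Girvan quality Q of a given partition."""
    a = _as_adjacency(adj).astype(float)
    k = a.sum(axis=1)
    m2 = k.sum()
    if m2 == 0:
        raise UndefinedMeasureError("modularity undefined on an edgeless graph")
    membership = np.asarray(membership)
    same = membership[:, None] == membership[None, :]
    return float(((a - np.outer(k, k) / m2) * same).sum() / m2)


@njit(cache=True)
def _spectral_split(Bg):
    """Leading-eigenvector bisection of a (generalized) modularity matrix,
    refined by Kernighan–Lin-style single-node moves.  Returns the sign
    vector s; all-ones when the matrix admits no improving split."""
    n = Bg.shape[0]
    s = np.ones(n)
    w, v = np.linalg.eigh(Bg)
    if w[n - 1] <= 1e-12:
        return s
    lead = v[:, n - 1]
    for i in range(n):
        s[i] = 1.0 if lead[i] >= 0.0 else -1.0
    diag = np.empty(n)
    for i in range(n):
        diag[i] = Bg[i, i]
    flips = np.empty(n, np.int64)
    for _ in range(15):  # refinement passes; each is a full KL sweep
        s_work = s.copy()
        Bs = Bg @ s_work
        obj = 0.0
        for i in range(n):
            obj += s_work[i] * Bs[i]
        best_obj = obj
        best_prefix = 0
        moved = np.zeros(n, np.bool_)
        for step in range(n):
            best_gain = -1e300
            best_i = -1
            for i in range(n):
                if moved[i]:
                    continue
                g = -4.0 * s_work[i] * Bs[i] + 4.0 * diag[i]
                if g > best_gain:
                    best_gain = g
                    best_i = i
            obj += best_gain
            s_work[best_i] = -s_work[best_i]
            for j in range(n):
                Bs[j] += 2.0 * Bg[j, best_i] * s_work[best_i]
            moved[best_i] = True
            flips[step] = best_i
            if obj > best_obj + 1e-12:
                best_obj = obj
                best_prefix = step + 1
        if best_prefix == 0:
            break
        for t in range(best_prefix):
            s[flips[t]] = -s[flips[t]]
    return s


def modularity(adj: np.ndarray, seed: int = 0) -> tuple[float, np.ndarray]:
    """Community structure by Newman's spectral algorithm.

    Communities are split recursively along the leading eigenvector of the
    generalized modularity matrix, each bisection refined by
    Kernighan–Lin-style node moves; a community is left intact when no
    split increases Q.  Tie-breaking (eigenvector entries at exactly zero)
    is deterministic, so results are reproducible for any ``seed``.

    Returns (Q, membership).
    """
    a = _as_adjacency(adj).astype(float)
    n = a.shape[0]
    k = a.sum(axis=1)
    m2 = k.sum()
    if m2 == 0:
        raise UndefinedMeasureError("modularity undefined on an edgeless graph")
    B = a - np.outer(k, k) / m2
    final: list[np.ndarray] = []
    stack: list[np.ndarray] = [np.arange(n)]
    while stack:
        nodes = stack.pop()
        if nodes.size == 1:
            final.append(nodes)
            continue
        Bg = B[np.ix_(nodes, nodes)].copy()
        Bg[np.diag_indices(nodes.size)] -= Bg.sum(axis=1)
        s = _spectral_split(np.ascontiguousarray(Bg))
        delta = s @ Bg @ s  # = 4m * deltaQ
        if delta <= 1e-12 or np.all(s == s[0]):
            final.append(nodes)
            continue
        stack.append(nodes[s > 0])
        stack.append(nodes[s < 0])
    membership = np.empty(n, dtype=np.int64)
    for label, nodes in enumerate(sorted(final, key=lambda c: int(c[0]))):
        membership[nodes] = label
    return modularity_q(a, membership), membership


def small_worldness(
    adj: np.ndarray,
    ensemble_size: int = 50,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> float:
    """σ = (C/C_rand)/(L/L_rand) against degree-preserving randomizations.

    Each reference network applies ``swaps_per_edge·|E|`` attempted
    double-edge swaps (invalid proposals skipped), preserving the degree
    sequence exactly.  On graphs that admit no swap (e.g. complete graphs)
    the ensemble reproduces the input and σ = 1.
    """
    a = _as_adjacency(adj)
    n = a.shape[0]
    iu, ju = np.nonzero(np.triu(a, 1))
    if iu.size == 0:
        raise UndefinedMeasureError("small-worldness undefined on an edgeless graph")
    c_obs = float(_kernels.clustering_coefficient(a, n))
    _, d_sum, reach = _kernels.distance_stats(a, n)
    if reach == 0:
        raise UndefinedMeasureError("small-worldness undefined: no connected pair")
    if reach < n * (n - 1):
        logger.debug("graph disconnected; path length over reachable pairs only")
    l_obs = d_sum / reach

    if n <= 64:
        c_ref, l_ref, swaps = _kernels.sigma_reference_stats(
            iu.astype(np.int32), ju.astype(np.int32), n,
            ensemble_size, swaps_per_edge, seed % 2**31,
        )
    else:
        rng = np.random.default_rng(seed)
        attempts = swaps_per_edge * iu.size
        shape = (ensemble_size, attempts)
        c_ref, l_ref, swaps = _kernels.sigma_ensemble(
            iu.astype(np.int32),
            ju.astype(np.int32),
            n,
            rng.integers(0, iu.size, shape),
            rng.integers(0, iu.size, shape),
            rng.integers(0, 2, shape).astype(np.bool_),
        )
    if swaps == 0:
        logger.warning("graph admits no degree-preserving swap; sigma = 1 by rigidity")
        return 1.0
    gamma = c_obs / c_ref if c_ref > 0 else (1.0 if c_obs == 0 else np.inf)
    lam = l_obs / l_ref if l_ref > 0 else 1.0
    return float(gamma / lam)


# ---------------------------------------------------------------------------
# measure curves over the density sweep
# ---------------------------------------------------------------------------

@dataclass
class MeasureCurve:
    """One global measure over the density grid (or a density-free scalar)."""

    measure_name: str
    values: Mapping[float, float] | float
    group: tuple[str, str] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def is_scalar(self) -> bool:
        return np.isscalar(self.values)

    def as_array(self) -> np.ndarray:
        if self.is_scalar:
            return np.asarray([self.values], dtype=float)
        return np.asarray(list(self.values.values()), dtype=float)

    def to_frame(self) -> pd.DataFrame:
        group = "-".join(self.group) if self.group else ""
        if self.is_scalar:
            rows = [{"group": group, "measure": self.measure_name,
                     "density": np.nan, "value": float(self.values)}]
        else:
            rows = [
                {"group": group, "measure": self.measure_name,
                 "density": d, "value": v}
                for d, v in self.values.items()
            ]
        return pd.DataFrame(rows)


def measure_over_stack(
    stack: BinaryGraphStack,
    measure: str,
    seed: int = 0,
    sw_ensemble: int = 50,
) -> np.ndarray:
    """Evaluate one binary measure at every density of a stack."""
    if measure == "global_efficiency":
        if stack.edge_counts is not None and stack.edge_i is not None:
            # incremental fast path exploiting nestedness
            n = stack.adjacency.shape[1]
            curve_fn = (
                _kernels.efficiency_curve_bits if n <= 64
                else _kernels.efficiency_curve
            )
            return np.asarray(
                curve_fn(stack.edge_i, stack.edge_j,
                         stack.edge_counts.astype(np.int64), n)
            )
        return np.array([global_efficiency(a) for a in stack.adjacency])
    if measure == "local_efficiency":
        return np.array([local_efficiency(a) for a in stack.adjacency])
    if measure == "modularity":
        return np.array([modularity(a, seed=seed)[0] for a in stack.adjacency])
    if measure == "small_worldness":
        rng = np.random.default_rng(seed)
        return np.array(
            [
                small_worldness(a, ensemble_size=sw_ensemble,
                                seed=int(rng.integers(2**31)))
                for a in stack.adjacency
            ]
        )
    raise ValueError(f"unknown density measure {measure!r}")


def compute_measures(
    conn: WeightedConnectome,
    d_min: float = 0.20,
    d_max: float = 0.60,
    step: float = 0.01,
    measures: tuple[str, ...] = MEASURES,
    seed: int = 0,
    sw_ensemble: int = 50,
) -> dict[str, MeasureCurve]:
    """All requested measures for one group connectome."""
    stack = build_stack(conn, d_min, d_max, step)
    out: dict[str, MeasureCurve] = {}
    for m in measures:
        if m == "strength":
            out[m] = MeasureCurve("strength", network_strength(conn), group=conn.group)
        else:
            vals = measure_over_stack(stack, m, seed=seed, sw_ensemble=sw_ensemble)
            out[m] = MeasureCurve(
                m,
                dict(zip((float(d) for d in stack.densities), map(float, vals))),
                group=conn.group,
                metadata={"sw_ensemble": sw_ensemble} if m == "small_worldness" else {},
            )
    return out
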