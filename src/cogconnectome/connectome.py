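"""Group-level cognitive connectomes and proportional density thresholding.

A group's connectome is the matrix of Pearson correlations between its
cognitive variables with self-connections removed and negative correlations
set to zero (absent).  Group comparisons require matched edge counts, so
binarization is proportional: at target density *d* the top
``k = round(d · n(n−1)/2)`` strongest positive correlations become edges.
Edges are ranked by a deterministic total order (descending weight, then
ascending node-pair labels), which makes the density stack nested: every
edge present at density *d* is present at all higher densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .design import Group

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedConnectome",
    "BinaryGraphStack",
    "density_grid",
    "build_connectome",
    "edge_ranking",
    "edge_count_at_density",
    "threshold_at_density",
    "build_stack",
    "select_density_range",
]

#: Published density sweep: 20% to 60% in steps of 1%.
DEFAULT_DENSITY_RANGE = (0.20, 0.60, 0.01)


def density_grid(
    d_min: float = 0.20, d_max: float = 0.60, step: float = 0.01
) -> np.ndarray:
    """Inclusive density grid, computed in integer steps to avoid float drift."""
    if not (0 < d_min < d_max <= 1) or step <= 0:
        raise ValueError("require 0 < d_min < d_max <= 1 and step > 0")
    n_steps = int(round((d_max - d_min) / step))
    return np.round(d_min + step * np.arange(n_steps + 1), 10)


@dataclass
class WeightedConnectome:
    """Nonnegative symmetric correlation network over the cognitive variables."""

    weights: np.ndarray
    node_labels: tuple[str, ...]
    group: Group | None = None
    n_participants: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] != len(self.node_labels):
            raise ValueError("node_labels length must match matrix size")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-connections must be removed (zero diagonal)")
        if np.any(w < 0):
            raise ValueError("negative correlations must be removed")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_pairs(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def n_positive_edges(self) -> int:
        iu, ju = np.triu_indices(self.n_nodes, 1)
        return int(np.count_nonzero(self.weights[iu, ju] > 0))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.weights, index=list(self.node_labels), columns=list(self.node_labels)
        ).to_csv(path)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        iu, ju = np.triu_indices(self.n_nodes, 1)
        for i, j in zip(iu, ju):
            w = self.weights[i, j]
            if w > 0:
                g.add_edge(self.node_labels[i], self.node_labels[j], weight=float(w))
        nx.write_graphml(g, path)

    @classmethod
    def from_csv(cls, path: str | Path, group: Group | None = None) -> "WeightedConnectome":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(dtype=float), tuple(frame.columns), group=group)


@dataclass
class BinaryGraphStack:
    """One binary adjacency per density of the (nested) sweep."""

    densities: np.ndarray
    adjacency: np.ndarray  # (n_densities, n, n) boolean
    node_labels: tuple[str, ...] = field(default_factory=tuple)
    edge_counts: np.ndarray | None = None
    #: edges in the deterministic ranking order (first k form level k)
    edge_i: np.ndarray | None = None
    edge_j: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.densities)

    def graph_at(self, density: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.densities - density)))
        if abs(self.densities[idx] - density) > 1e-9:
            raise KeyError(f"density {density} not on the grid")
        return self.adjacency[idx]

    def to_edgelists(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        labels = list(self.node_labels)
        for d, adj in zip(self.densities, self.adjacency):
            iu, ju = np.nonzero(np.triu(adj, 1))
            frame = pd.DataFrame(
                {"source": [labels[i] for i in iu], "target": [labels[j] for j in ju]}
            )
            frame.to_csv(directory / f"edges_density_{int(round(d * 100)):02d}.tsv",
                         sep="\t", index=False)


def build_connectome(
    group_data: np.ndarray | pd.DataFrame,
    node_labels: Sequence[str] | None = None,
    group: Group | None = None,
) -> WeightedConnectome:
    """Pearson-correlation network of one group's z-score matrix.

    ``w_ij = max(0, pearson(x_i, x_j))`` for i ≠ j, ``w_ii = 0``.
    """
    if isinstance(group_data, pd.DataFrame):
        if node_labels is None:
            node_labels = tuple(group_data.columns)
        group_data = group_data.to_numpy(dtype=float)
    x = np.asarray(group_data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a participants x variables matrix with >= 3 rows")
    if node_labels is None:
        node_labels = tuple(f"v{i}" for i in range(x.shape[1]))
    sd = x.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [node_labels[i] for i in constant]
        raise ValueError(
            f"constant variables in group {group}: {names} (correlation undefined)"
        )
    r = np.corrcoef(x, rowvar=False)
    w = np.clip(r, 0.0, None)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    return WeightedConnectome(
        w, tuple(node_labels), group=group, n_participants=x.shape[0]
    )


def edge_ranking(conn: WeightedConnectome) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positive edges sorted by the deterministic total order.

    Returns (i, j, w) arrays sorted by descending weight, ties broken by
    ascending (i, j) label order.
    """
    n = conn.n_nodes
    iu, ju = np.triu_indices(n, 1)
    w = conn.weights[iu, ju]
    pos = w > 0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    order = np.lexsort((ju, iu, -w))
    return iu[order].astype(np.int32), ju[order].astype(np.int32), w[order]


def edge_count_at_density(density: float, n_pairs: int) -> int:
    """Target edge count: round-half-away-from-zero of density · n_pairs."""
    return int(np.floor(density * n_pairs + 0.5))


def threshold_at_density(conn: WeightedConnectome, density: float) -> np.ndarray:
    """Binary adjacency keeping the k strongest positive correlations.

    If fewer than k positive correlations exist, all are kept and the
    realized density is logged.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density {density} outside (0, 1]")
    ei, ej, _ = edge_ranking(conn)
    k = edge_count_at_density(density, conn.n_pairs)
    if k > ei.size:
        logger.warning(
            "only %d positive edges available for target density %.2f "
            "(realized density %.3f)", ei.size, density, ei.size / conn.n_pairs,
        )
        k = ei.size
    n = conn.n_nodes
    adj = np.zeros((n, n), dtype=bool)
    adj[ei[:k], ej[:k]] = True
    adj[ej[:k], ei[:k]] = True
    return adj


def build_stack(
    conn: WeightedConnectome,
    d_min: float = DEFAULT_DENSITY_RANGE[0],
    d_max: float = DEFAULT_DENSITY_RANGE[1],
    step: float = DEFAULT_DENSITY_RANGE[2],
) -> BinaryGraphStack:
    """Thresholded adjacency at every grid density; nested by construction."""
    densities = density_grid(d_min, d_max, step)
    ei, ej, _ = edge_ranking(conn)
    ks = np.minimum(
        np.array([edge_count_at_density(d, conn.n_pairs) for d in densities]),
        ei.size,
    )
    n = conn.n_nodes
    ranks = np.arange(ei.size)
    include = ranks[None, :] < ks[:, None]  # (densities, edges)
    adjacency = np.zeros((len(densities), n, n), dtype=bool)
    adjacency[:, ei, ej] = include
    adjacency[:, ej, ei] = include
    return BinaryGraphStack(
        densities=densities,
        adjacency=adjacency,
        node_labels=conn.node_labels,
        edge_counts=ks,
        edge_i=ei,
        edge_j=ej,
    )


def select_density_range(
    conn: WeightedConnectome,
    candidate_grid: np.ndarray | None = None,
    sw_ensemble: int = 20,
    sw_seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Data-driven density window for a pooled-cohort connectome.

    The lower bound is the smallest grid density whose graph is connected
    (a single component spanning every node); the upper bound is the
    largest grid density whose small-worldness σ is still ≥ 1 (denser
    graphs approach random topology).  Returns (d_min, d_max, diagnostics).
    """
    from .measures import small_worldness

    if candidate_grid is None:
        candidate_grid = density_grid(0.05, 1.0, 0.01)
    candidate_grid = np.asarray(candidate_grid, dtype=float)
    ei, ej, _ = edge_ranking(conn)
    n = conn.n_nodes
    rows = []
    d_min = None
    d_max = None
    for d in candidate_grid:
        k = min(edge_count_at_density(d, conn.n_pairs), ei.size)
        adj = np.zeros((n, n), dtype=bool)
        adj[ei[:k], ej[:k]] = True
        adj[ej[:k], ei[:k]] = True
        is_conn = bool(_kernels.connected(adj, n))
        sigma = np.nan
        if is_conn:
            if d_min is None:
                d_min = float(d)
            sigma = small_worldness(adj, ensemble_size=sw_ensemble, seed=sw_seed)
            if sigma >= 1:
                d_max = float(d)
        rows.append({"density": float(d), "n_edges": int(k),
                     "connected": is_conn, "sigma": sigma})
    diagnostics = pd.DataFrame(rows)
    if d_min is None:
        raise ValueError("no candidate density yields a connected graph")
    if d_max is None or d_max < d_min:
        raise ValueError("no density at or above the connectivity bound has sigma >= 1")
    return d_min, d_max, diagnostics
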