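"""Binary network construction from streamline counts.

A subject's tractography output is reduced to a symmetric matrix of
streamline counts between atlas regions; an undirected, unweighted edge
is drawn wherever the count reaches the fiber-number (FN) threshold
(default 3).  Thresholds 1-5 are swept to check robustness of downstream
topological results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityCountMatrix",
    "BinaryNetwork",
    "DEFAULT_FN",
    "count_streamlines",
    "threshold_network",
    "sweep_thresholds",
]

DEFAULT_FN = 3  # minimum streamline count for an edge


def _check_square_symmetric(m: np.ndarray, what: str) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{what} must be a square matrix, got shape {m.shape}")
    bad = np.argwhere(m != m.T)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{what} is asymmetric: entry ({i},{j})={m[i, j]} != ({j},{i})={m[j, i]}"
        )
    if np.any(np.diag(m) != 0):
        i = int(np.flatnonzero(np.diag(m))[0])
        raise ValueError(f"{what} has nonzero diagonal at node {i}")


@dataclass
class ConnectivityCountMatrix:
    """Symmetric non-negative integer streamline counts for one subject."""

    counts: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts).astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("streamline counts must be integers")
            self.counts = as_int
        _check_square_symmetric(self.counts, "count matrix")
        if np.any(self.counts < 0):
            raise ValueError("streamline counts must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted network over the atlas node set.

    The adjacency matrix is symmetric {0,1} with a zero diagonal.
    Isolated nodes are retained; every metric must handle them.
    """

    adjacency: np.ndarray
    node_labels: list[str] | None = field(default=None)
    validate: bool = True

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        if self.validate:
            _check_square_symmetric(self.adjacency, "adjacency")
            if not np.isin(self.adjacency, (0, 1)).all():
                raise ValueError("adjacency entries must be 0 or 1")
            if self.node_labels is not None and len(self.node_labels) != self.n_nodes:
                raise ValueError("node_labels length must equal n_nodes")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> np.ndarray:
        """Edges as an (m, 2) array with first index < second."""
        iu, ju = np.triu_indices(self.n_nodes, 1)
        on = self.adjacency[iu, ju] > 0
        return np.column_stack([iu[on], ju[on]])

    def copy(self) -> "BinaryNetwork":
        return BinaryNetwork(self.adjacency.copy(), self.node_labels, validate=False)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edge_list()))
        return g


def count_streamlines(table: pd.DataFrame, n_nodes: int) -> ConnectivityCountMatrix:
    """Tally a streamline table into a symmetric count matrix.

    Parameters
    ----------
    table
        One row per reconstructed streamline, with integer columns
        ``region_a`` and ``region_b`` (endpoints, order irrelevant) and
        optionally ``subject_id``.
    n_nodes
        Number of atlas regions; all endpoints must be < n_nodes.
    """
    a = np.asarray(table["region_a"], dtype=np.int64)
    b = np.asarray(table["region_b"], dtype=np.int64)
    self_rows = np.flatnonzero(a == b)
    if self_rows.size:
        r = int(self_rows[0])
        raise ValueError(f"streamline row {r} is a self-pair (region {a[r]})")
    if a.size and (a.min() < 0 or b.min() < 0 or a.max() >= n_nodes or b.max() >= n_nodes):
        raise ValueError(f"streamline endpoint outside atlas range [0, {n_nodes})")
    counts = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    np.add.at(counts, (b, a), 1)
    subject_id = ""
    if "subject_id" in table.columns and len(table):
        subject_id = str(table["subject_id"].iloc[0])
    return ConnectivityCountMatrix(counts, subject_id=subject_id)


def threshold_network(
    counts: ConnectivityCountMatrix,
    fn: int = DEFAULT_FN,
    node_labels: list[str] | None = None,
) -> BinaryNetwork:
    """Binarize a count matrix: edge iff at least ``fn`` streamlines."""
    fn = int(fn)
    if fn < 1:
        raise ValueError(f"FN threshold must be >= 1, got {fn}")
    adj = (counts.counts >= fn).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(adj, node_labels=node_labels, validate=False)


def sweep_thresholds(
    counts: ConnectivityCountMatrix,
    fn_values: list[int] = (1, 2, 3, 4, 5),
    node_labels: list[str] | None = None,
) -> dict[int, BinaryNetwork]:
    """One binary network per FN threshold; edge sets are nested in fn."""
    fn_values = list(fn_values)
    if not fn_values:
        raise ValueError("fn_values must be non-empty")
    return {int(f): threshold_network(counts, f, node_labels) for f in fn_values}
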