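"""Global and nodal graph-theory metrics for binary networks.

Global parameters
-----------------
Cp    mean Watts-Strogatz clustering coefficient over all nodes
Lp    characteristic path length: mean of the finite shortest-path
      distances over all reachable ordered pairs (the fraction of
      unreachable pairs is reported alongside)
locE  mean neighborhood-subgraph global efficiency
gE    mean inverse shortest-path distance over ordered pairs (1/inf = 0)
gamma, lambda, sigma
      Cp and Lp normalized by a degree-preserving random ensemble and
      their ratio sigma = gamma/lambda (see :mod:`wmnet.nulls`);
      sigma > 1 indicates small-world organization.

Nodal centralities
------------------
Di  degree; Ei  nodal efficiency (mean inverse distance to the other
nodes); Bi  unnormalized Brandes betweenness (each unordered pair of
endpoints counted once, endpoints excluded); plus the per-node
clustering coefficient and per-node mean shortest path length used by
hub scoring.

Conventions for degenerate cases follow common connectome toolboxes:
nodes of degree < 2 have clustering 0 and contribute 0 to locE; an
isolated node has Ei = 0 and an undefined (NaN) nodal path length.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .construction import BinaryNetwork

__all__ = [
    "GlobalMetrics",
    "shortest_paths",
    "clustering",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "degree_centrality",
    "betweenness_centrality",
    "compute_all",
]

NODAL_COLUMNS = ["degree", "efficiency", "betweenness", "clustering", "path_length"]


@dataclass
class GlobalMetrics:
    """Whole-network parameters; normalized ones are NaN without a null ensemble."""

    cp: float
    lp: float
    loce: float
    ge: float
    gamma: float = float("nan")
    lam: float = float("nan")
    sigma: float = float("nan")
    disconnected_pair_fraction: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "cp": self.cp,
            "lp": self.lp,
            "loce": self.loce,
            "ge": self.ge,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
            "disconnected_pair_fraction": self.disconnected_pair_fraction,
        }


# ---------------------------------------------------------------------------
# distances


def shortest_paths(net: BinaryNetwork) -> np.ndarray:
    """All-pairs hop distances; ``inf`` for unreachable pairs, 0 diagonal."""
    return _distances_from_adjacency(net.adjacency)


def _distances_from_adjacency(adj: np.ndarray) -> np.ndarray:
    return _csgraph_shortest_path(
        csr_matrix(adj), method="D", unweighted=True, directed=False
    )


# ---------------------------------------------------------------------------
# clustering


def clustering(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node Watts-Strogatz clustering and its mean Cp.

    ci = 2 * (edges among neighbors of i) / (ki * (ki - 1)); nodes with
    ki < 2 get ci = 0.  Cp averages ci over *all* nodes, isolated
    included.
    """
    ci = _clustering_from_adjacency(net.adjacency.astype(np.float64))
    return ci, float(ci.mean())


def _clustering_from_adjacency(a: np.ndarray) -> np.ndarray:
    k = a.sum(axis=1)
    # (A^3)_ii counts closed 3-walks = 2 * triangles at i
    closed = ((a @ a) * a).sum(axis=1)
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(denom > 0, closed / denom, 0.0)
    return ci


# ---------------------------------------------------------------------------
# path length / efficiency


def characteristic_path_length(dm: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Nodal and global characteristic path length from a distance matrix.

    Returns ``(li, lp, disconnected_pair_fraction)``.  li is the mean
    finite distance from node i to the nodes it can reach (NaN if it can
    reach none); Lp is the mean over all finite off-diagonal ordered
    pairs (NaN for an edgeless network).
    """
    n = dm.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dm) & off
    n_off = n * (n - 1)
    frac = 1.0 - finite.sum() / n_off if n_off else 0.0
    row_counts = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        li = np.where(
            row_counts > 0,
            np.where(finite, dm, 0.0).sum(axis=1) / np.maximum(row_counts, 1),
            np.nan,
        )
    lp = float(dm[finite].mean()) if finite.any() else float("nan")
    return li, lp, float(frac)


def global_efficiency(dm: np.ndarray) -> tuple[np.ndarray, float]:
    """Nodal efficiency Ei and global efficiency gE (mean inverse distance)."""
    n = dm.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / dm
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    if n < 2:
        return np.zeros(n), 0.0
    ei = inv.sum(axis=1) / (n - 1)
    ge = float(inv.sum() / (n * (n - 1)))
    return ei, ge


def local_efficiency(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Per-node efficiency of the neighbor-induced subgraph and its mean locE."""
    a = net.adjacency
    n = net.n_nodes
    vals = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        _, vals[i] = global_efficiency(_distances_from_adjacency(sub))
    return vals, float(vals.mean()) if n else 0.0


# ---------------------------------------------------------------------------
# centralities


def degree_centrality(net: BinaryNetwork) -> np.ndarray:
    return net.degrees


def betweenness_centrality(net: BinaryNetwork) -> np.ndarray:
    """Unnormalized Brandes betweenness (unordered pairs, endpoints excluded)."""
    bc = nx.betweenness_centrality(net.to_networkx(), normalized=False)
    return np.array([bc[i] for i in range(net.n_nodes)], dtype=np.float64)


# ---------------------------------------------------------------------------
# assembly


def compute_all(net: BinaryNetwork, nulls=None) -> tuple[GlobalMetrics, pd.DataFrame]:
    """All global and nodal metrics for one network.

    Parameters
    ----------
    net
        The binary network.
    nulls
        Optional :class:`wmnet.nulls.NullEnsemble` built from this
        network; when given, gamma/lambda/sigma are filled in.

    Returns
    -------
    (GlobalMetrics, DataFrame)
        The nodal table has columns ``degree``, ``efficiency``,
        ``betweenness``, ``clustering``, ``path_length`` indexed by node,
        plus ``label`` when the network carries node labels.
    """
    dm = shortest_paths(net)
    ci, cp = clustering(net)
    li, lp, frac = characteristic_path_length(dm)
    ei, ge = global_efficiency(dm)
    _, loce = local_efficiency(net)
    di = degree_centrality(net)
    bi = betweenness_centrality(net)

    gm = GlobalMetrics(cp=cp, lp=lp, loce=loce, ge=ge, disconnected_pair_fraction=frac)
    if nulls is not None:
        from .nulls import normalized_metrics

        nm = normalized_metrics(net, nulls, cp_real=cp, lp_real=lp)
        gm.gamma, gm.lam, gm.sigma = nm.gamma, nm.lam, nm.sigma

    nodal = pd.DataFrame(
        {
            "degree": di,
            "efficiency": ei,
            "betweenness": bi,
            "clustering": ci,
            "path_length": li,
        }
    )
    nodal.index.name = "node"
    if net.node_labels is not None:
        nodal.insert(0, "label", net.node_labels)
    return gm, nodal
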