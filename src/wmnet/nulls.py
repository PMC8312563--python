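"""Degree-preserving null models and normalized small-world parameters.

Raw Cp and Lp depend on density and degree sequence, so they are
normalized against an ensemble of Maslov-Sneppen rewired surrogates that
keep every node's degree fixed: gamma = Cp / <Cp_null>,
lambda = Lp / <Lp_null>, sigma = gamma / lambda.  A rewired surrogate is
produced by repeated double-edge swaps (a,b),(c,d) -> (a,d),(c,b); swaps
that would create a self-loop or duplicate edge are skipped (and
counted), which preserves the degree sequence exactly.

Connectedness is deliberately not enforced during rewiring (that would
bias the null); ensemble members whose Lp is undefined are excluded from
the Lp average and their count reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .construction import BinaryNetwork
from .metrics import _clustering_from_adjacency, _distances_from_adjacency, characteristic_path_length

__all__ = [
    "NullEnsemble",
    "NormalizedMetrics",
    "rewire_degree_preserving",
    "build_ensemble",
    "normalized_metrics",
    "DEFAULT_ENSEMBLE_SIZE",
    "DEFAULT_SWAP_FACTOR",
]

DEFAULT_ENSEMBLE_SIZE = 100
DEFAULT_SWAP_FACTOR = 10.0


@dataclass
class NullEnsemble:
    networks: list[BinaryNetwork]
    source_degree_sequence: np.ndarray
    seed: int | None = None

    @property
    def m(self) -> int:
        return len(self.networks)


@dataclass
class NormalizedMetrics:
    gamma: float
    lam: float
    sigma: float
    n_undefined_lp: int = 0


def rewire_degree_preserving(
    net: BinaryNetwork,
    swap_factor: float = DEFAULT_SWAP_FACTOR,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BinaryNetwork:
    """One Maslov-Sneppen rewired surrogate of ``net``.

    Attempts ``round(swap_factor * n_edges)`` double-edge swaps; each
    candidate swap is rejected (skipped) if it would create a self-loop
    or a duplicate edge.  The degree sequence is preserved exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    edges = [tuple(e) for e in net.edge_list()]
    m = len(edges)
    if m < 2:
        return net.copy()
    edge_set = {e for e in edges}
    n_attempts = int(round(swap_factor * m))
    pick = rng.integers(0, m, size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        i, j = pick[t]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip[t]:
            c, d = d, c
        # proposed new edges: (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
    adj = np.zeros_like(net.adjacency)
    if edges:
        arr = np.asarray(edges)
        adj[arr[:, 0], arr[:, 1]] = 1
        adj[arr[:, 1], arr[:, 0]] = 1
    return BinaryNetwork(adj, net.node_labels, validate=False)


def build_ensemble(
    net: BinaryNetwork,
    m: int = DEFAULT_ENSEMBLE_SIZE,
    swap_factor: float = DEFAULT_SWAP_FACTOR,
    seed: int = 0,
) -> NullEnsemble:
    """m independent rewired surrogates; member i uses seed ``seed + i``."""
    if m < 1:
        raise ValueError("ensemble size m must be >= 1")
    members = [
        rewire_degree_preserving(net, swap_factor=swap_factor, seed=seed + i)
        for i in range(m)
    ]
    return NullEnsemble(members, net.degrees.copy(), seed=seed)


def normalized_metrics(
    net: BinaryNetwork,
    ensemble: NullEnsemble,
    cp_real: float | None = None,
    lp_real: float | None = None,
) -> NormalizedMetrics:
    """gamma, lambda, sigma of ``net`` against its null ensemble.

    ``cp_real``/``lp_real`` may be passed to avoid recomputation.
    Ensemble members with undefined Lp (edgeless after rewiring cannot
    happen, but fully disconnected metrics can in principle) are skipped
    for the Lp mean and counted.
    """
    a = net.adjacency.astype(np.float64)
    if cp_real is None:
        cp_real = float(_clustering_from_adjacency(a).mean())
    if lp_real is None:
        _, lp_real, _ = characteristic_path_length(_distances_from_adjacency(a))

    cps = np.empty(ensemble.m)
    lps = np.full(ensemble.m, np.nan)
    for k, member in enumerate(ensemble.networks):
        ma = member.adjacency.astype(np.float64)
        cps[k] = _clustering_from_adjacency(ma).mean()
        _, lps[k], _ = characteristic_path_length(_distances_from_adjacency(ma))
    defined = np.isfinite(lps)
    n_undef = int(ensemble.m - defined.sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = float(cp_real / cps.mean()) if cps.mean() > 0 else float("nan")
        lam = float(lp_real / lps[defined].mean()) if defined.any() else float("nan")
        sigma = gamma / lam if lam and np.isfinite(lam) and lam > 0 else float("nan")
    return NormalizedMetrics(gamma=gamma, lam=lam, sigma=sigma, n_undefined_lp=n_undef)
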