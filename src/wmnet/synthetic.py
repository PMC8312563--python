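"""Synthetic two-group connectome cohort generator.

Emulates the data structure the analysis pipeline assumes, so that every
downstream stage is testable without diffusion MRI: a shared small-world
base topology (rewired ring lattice over 90 regions), per-subject
variants (extra randomization and targeted degree deficits for the
patient group, plus per-subject edge noise), Poisson streamline counts
on top of the binary truth, and a metadata table with demographic
covariates and clinical variables.  Clinical variables are rank-coupled
to each patient's realized characteristic path length so that the
configured monotone association holds without distributional
commitments.

The generator defaults mirror the study cohort it emulates: 91 controls
vs 145 patients, age ~38.5 +/- 12 years, education ~13 +/- 3.5 years,
PTA 12 dB HL (controls) vs 78 dB HL (patients), THI ~46 +/- 25,
duration ~8 +/- 4 days, and a patient-side topology shift toward
randomization (extra rewiring 0.3) with degree deficits at designated
nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

from .construction import BinaryNetwork, ConnectivityCountMatrix

__all__ = [
    "CohortConfig",
    "generate_base_topology",
    "plant_hubs",
    "generate_subject_network",
    "sample_counts",
    "generate_cohort",
    "expand_to_streamlines",
]

# default planted structure, indices in the AAL-90 ordering:
# hubs at PreCG.L/R (0,1), PCUN.L/R (66,67), PUT.L/R (72,73);
# patient degree deficits at IFGoperc.R (11) and PUT.L/R (72,73)
DEFAULT_HUB_NODES = (0, 1, 66, 67, 72, 73)
DEFAULT_DEFICIT_NODES = {11: 0.3, 72: 0.3, 73: 0.3}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; defaults emulate the study cohort."""

    n_controls: int = 91
    n_patients: int = 145
    n_nodes: int = 90
    base_mean_degree: int = 6
    base_rewire_prob: float = 0.1
    patient_extra_rewire: float = 0.3
    patient_edge_loss: float = 0.2
    subject_edge_noise: float = 0.01
    planted_hub_nodes: tuple[int, ...] = DEFAULT_HUB_NODES
    hub_extra_degree: int = 8
    planted_deficit_nodes: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DEFICIT_NODES)
    )
    count_mean_present: float = 20.0
    count_mean_absent: float = 0.05
    age_mean: float = 38.5
    age_sd: float = 12.0
    male_proportion: float = 0.5
    education_mean: float = 13.0
    education_sd: float = 3.5
    pta_hc_mean: float = 12.08
    pta_hc_sd: float = 4.04
    pta_patient_mean: float = 78.17
    pta_patient_sd: float = 28.56
    thi_mean: float = 45.57
    thi_sd: float = 24.88
    duration_mean: float = 8.44
    duration_sd: float = 4.17
    thi_corr: float = 0.18
    duration_corr: float = -0.18
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be >= 4")
        if self.base_mean_degree % 2 or not 2 <= self.base_mean_degree < self.n_nodes:
            raise ValueError("base_mean_degree must be even and in [2, n_nodes)")
        for name in ("base_rewire_prob", "patient_extra_rewire", "patient_edge_loss",
                     "subject_edge_noise", "male_proportion"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.count_mean_present > self.count_mean_absent >= 0:
            raise ValueError("require count_mean_present > count_mean_absent >= 0")
        if self.n_controls < 1 or self.n_patients < 1:
            raise ValueError("both groups must be non-empty")
        for i in (*self.planted_hub_nodes, *self.planted_deficit_nodes):
            if not 0 <= i < self.n_nodes:
                raise ValueError(f"planted node index {i} outside [0, {self.n_nodes})")
        for i, f in self.planted_deficit_nodes.items():
            if not 0 <= f <= 1:
                raise ValueError(f"deficit fraction for node {i} must lie in [0, 1]")
        for name in ("thi_corr", "duration_corr"):
            if not -1 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# network generation


def _as_rng(seed, rng):
    return rng if rng is not None else np.random.default_rng(seed)


def _rewire_edges(adj: np.ndarray, prob: float, rng: np.random.Generator) -> None:
    """Watts-Strogatz-style rewiring, in place.

    Each current edge, visited in canonical order, is rewired with
    probability ``prob``: one endpoint (chosen at random) is kept as the
    anchor and the other is replaced by a uniformly chosen node that is
    neither the anchor nor already adjacent to it.  Edge count is
    conserved; an edge whose anchor is already connected to everyone is
    left untouched.
    """
    n = adj.shape[0]
    iu, ju = np.triu_indices(n, 1)
    on = adj[iu, ju] > 0
    for u, v in zip(iu[on], ju[on]):
        if adj[u, v] == 0:  # may have been moved by an earlier rewire
            continue
        if rng.random() >= prob:
            continue
        anchor, other = (u, v) if rng.random() < 0.5 else (v, u)
        candidates = np.flatnonzero(adj[anchor] == 0)
        candidates = candidates[candidates != anchor]
        if candidates.size == 0:
            continue
        w = int(rng.choice(candidates))
        adj[anchor, other] = adj[other, anchor] = 0
        adj[anchor, w] = adj[w, anchor] = 1


def generate_base_topology(
    n_nodes: int,
    mean_degree: int,
    rewire_prob: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BinaryNetwork:
    """Rewired ring lattice (small-world substrate).

    Each node is first linked to its ``mean_degree`` nearest ring
    neighbors; each edge is then independently rewired with probability
    ``rewire_prob``.  Edge count n*k/2 is conserved.
    """
    if n_nodes < 4:
        raise ValueError("n_nodes must be >= 4")
    if mean_degree % 2 or not 2 <= mean_degree < n_nodes:
        raise ValueError("mean_degree must be even and in [2, n_nodes)")
    rng = _as_rng(seed, rng)
    adj = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    for off in range(1, mean_degree // 2 + 1):
        idx = np.arange(n_nodes)
        adj[idx, (idx + off) % n_nodes] = 1
        adj[(idx + off) % n_nodes, idx] = 1
    if rewire_prob > 0:
        _rewire_edges(adj, rewire_prob, rng)
    return BinaryNetwork(adj, validate=False)


def plant_hubs(
    net: BinaryNetwork,
    hub_nodes,
    extra_degree: int,
    rng: np.random.Generator,
) -> BinaryNetwork:
    """Attach ``extra_degree`` additional random edges to each hub node."""
    adj = net.adjacency.copy()
    n = net.n_nodes
    for h in hub_nodes:
        candidates = np.flatnonzero(adj[h] == 0)
        candidates = candidates[candidates != h]
        take = min(extra_degree, candidates.size)
        if take:
            chosen = rng.choice(candidates, size=take, replace=False)
            adj[h, chosen] = 1
            adj[chosen, h] = 1
    return BinaryNetwork(adj, net.node_labels, validate=False)


def generate_subject_network(
    base: BinaryNetwork,
    extra_rewire: float = 0.0,
    edge_noise: float = 0.0,
    deficit_spec: dict[int, float] | None = None,
    edge_loss: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BinaryNetwork:
    """Per-subject variant of the base topology.

    Applies, in order: extra Watts-Strogatz rewiring of a fraction
    ``extra_rewire`` of edges (the patient-group randomization shift),
    uniform deletion of a fraction ``edge_loss`` of all edges (global
    hypoconnectivity: raises path length and lowers the efficiencies),
    removal of the specified fraction of edges incident to each deficit
    node (rounded down, uniformly chosen), and independent edge flips at
    rate ``edge_noise`` (per-subject measurement noise).
    """
    rng = _as_rng(seed, rng)
    adj = base.adjacency.copy()
    n = base.n_nodes
    if extra_rewire > 0:
        _rewire_edges(adj, extra_rewire, rng)
    if edge_loss > 0:
        iu, ju = np.triu_indices(n, 1)
        on = np.flatnonzero(adj[iu, ju] > 0)
        n_drop = int(np.floor(edge_loss * on.size))
        if n_drop:
            drop = rng.choice(on, size=n_drop, replace=False)
            adj[iu[drop], ju[drop]] = 0
            adj[ju[drop], iu[drop]] = 0
    for node, frac in (deficit_spec or {}).items():
        if not 0 <= node < n:
            raise ValueError(f"deficit node {node} outside [0, {n})")
        incident = np.flatnonzero(adj[node])
        n_remove = int(np.floor(frac * incident.size))
        if n_remove:
            drop = rng.choice(incident, size=n_remove, replace=False)
            adj[node, drop] = 0
            adj[drop, node] = 0
    if edge_noise > 0:
        iu, ju = np.triu_indices(n, 1)
        flips = rng.random(iu.size) < edge_noise
        adj[iu[flips], ju[flips]] ^= 1
        adj[ju[flips], iu[flips]] ^= 1
    return BinaryNetwork(adj, base.node_labels, validate=False)


def sample_counts(
    net: BinaryNetwork,
    mean_present: float = 20.0,
    mean_absent: float = 0.05,
    subject_id: str = "",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ConnectivityCountMatrix:
    """Poisson streamline counts over the binary truth.

    Counts on true edges have mean ``mean_present``; spurious counts on
    non-edges have mean ``mean_absent``.  Means are chosen by default so
    the FN=3 edge rule is a high-fidelity detector.
    """
    if not mean_present > mean_absent >= 0:
        raise ValueError("require mean_present > mean_absent >= 0")
    rng = _as_rng(seed, rng)
    n = net.n_nodes
    iu, ju = np.triu_indices(n, 1)
    lam = np.where(net.adjacency[iu, ju] > 0, mean_present, mean_absent)
    vals = rng.poisson(lam)
    counts = np.zeros((n, n), dtype=np.int64)
    counts[iu, ju] = vals
    counts[ju, iu] = vals
    return ConnectivityCountMatrix(counts, subject_id=subject_id)


def expand_to_streamlines(counts: ConnectivityCountMatrix, subject_id: str = "") -> pd.DataFrame:
    """One row per streamline; exact inverse of count tallying."""
    n = counts.n_nodes
    iu, ju = np.triu_indices(n, 1)
    reps = counts.counts[iu, ju]
    a = np.repeat(iu, reps)
    b = np.repeat(ju, reps)
    sid = subject_id or counts.subject_id
    return pd.DataFrame({"subject_id": sid, "region_a": a, "region_b": b})


# ---------------------------------------------------------------------------
# cohort assembly


def _rank_couple(
    x: np.ndarray, marginal: np.ndarray, target_r: float, rng: np.random.Generator
) -> np.ndarray:
    """Couple a drawn marginal sample to x with a target monotone association.

    Normal scores of x are mixed with independent noise to form a latent
    variable with correlation ``target_r`` to x; the sorted marginal
    sample is then assigned by latent rank, preserving the marginal
    exactly while inducing the monotone coupling.
    """
    n = x.size
    zx = sps.norm.ppf((sps.rankdata(x) - 0.5) / n)
    latent = target_r * zx + np.sqrt(max(0.0, 1 - target_r**2)) * rng.standard_normal(n)
    out = np.empty(n)
    out[np.argsort(latent)] = np.sort(marginal)
    return out


def _subject_lp(net: BinaryNetwork) -> float:
    from .metrics import characteristic_path_length, shortest_paths

    _, lp, _ = characteristic_path_length(shortest_paths(net))
    return lp


def generate_cohort(
    config: CohortConfig,
) -> tuple[dict[str, ConnectivityCountMatrix], pd.DataFrame]:
    """Simulate the full two-group cohort.

    Returns the per-subject streamline-count matrices and the cohort
    metadata table (subject_id, group, age, gender, education, pta, thi,
    duration; clinical variables are NaN for controls).  Fully
    deterministic given the config (including its seed).
    """
    config.validate()
    master = np.random.default_rng(config.seed)

    base = generate_base_topology(
        config.n_nodes, config.base_mean_degree, config.base_rewire_prob, rng=master
    )
    base = plant_hubs(base, config.planted_hub_nodes, config.hub_extra_degree, master)

    n_total = config.n_controls + config.n_patients
    subject_seeds = master.integers(0, 2**31 - 1, size=n_total)

    matrices: dict[str, ConnectivityCountMatrix] = {}
    patient_lp = np.empty(config.n_patients)
    ids, groups = [], []
    for s in range(n_total):
        is_patient = s >= config.n_controls
        sid = (
            f"SS{s - config.n_controls + 1:03d}" if is_patient else f"HC{s + 1:03d}"
        )
        rng_s = np.random.default_rng(subject_seeds[s])
        net = generate_subject_network(
            base,
            extra_rewire=config.patient_extra_rewire if is_patient else 0.0,
            edge_noise=config.subject_edge_noise,
            deficit_spec=config.planted_deficit_nodes if is_patient else None,
            edge_loss=config.patient_edge_loss if is_patient else 0.0,
            rng=rng_s,
        )
        if is_patient:
            patient_lp[s - config.n_controls] = _subject_lp(net)
        matrices[sid] = sample_counts(
            net,
            config.count_mean_present,
            config.count_mean_absent,
            subject_id=sid,
            rng=rng_s,
        )
        ids.append(sid)
        groups.append("SSNHL" if is_patient else "HC")

    # covariates and clinical variables, in a fixed draw order
    age = np.clip(master.normal(config.age_mean, config.age_sd, n_total), 18, 80)
    gender = (master.random(n_total) < config.male_proportion).astype(int)  # 1 = male
    education = np.clip(
        master.normal(config.education_mean, config.education_sd, n_total), 0, 25
    )
    pta = np.where(
        np.array(groups) == "HC",
        master.normal(config.pta_hc_mean, config.pta_hc_sd, n_total),
        master.normal(config.pta_patient_mean, config.pta_patient_sd, n_total),
    )
    pta = np.clip(pta, 0, None)

    thi = np.full(n_total, np.nan)
    duration = np.full(n_total, np.nan)
    thi_marg = np.clip(
        master.normal(config.thi_mean, config.thi_sd, config.n_patients), 0, 100
    )
    dur_marg = np.clip(
        master.normal(config.duration_mean, config.duration_sd, config.n_patients),
        1,
        None,
    )
    pt_slice = slice(config.n_controls, n_total)
    thi[pt_slice] = _rank_couple(patient_lp, thi_marg, config.thi_corr, master)
    duration[pt_slice] = _rank_couple(patient_lp, dur_marg, config.duration_corr, master)

    table = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "age": age,
            "gender": gender,
            "education": education,
            "pta": pta,
            "thi": thi,
            "duration": duration,
        }
    )
    return matrices, table
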