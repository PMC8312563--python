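"""End-to-end orchestration: simulate/load -> construct -> metrics ->
nulls -> hubs -> statistics -> report tables on disk.

All tabular outputs are tab-separated with a header row; the run summary
is JSON.  A run is fully determined by its configuration (including the
seed): per-subject and per-threshold null-ensemble seeds are derived
from the run seed in a fixed order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .construction import BinaryNetwork, ConnectivityCountMatrix, sweep_thresholds
from .hubs import compare_hubs, group_nodal_means, hubness_scores
from .metrics import (
    GlobalMetrics,
    characteristic_path_length,
    clustering,
    compute_all,
    global_efficiency,
    local_efficiency,
    shortest_paths,
)
from .nulls import build_ensemble, normalized_metrics
from .stats import run_group_analysis
from .synthetic import CohortConfig, generate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "simulate_to_disk"]

log = logging.getLogger("wmnet")


@dataclass
class RunConfig:
    mode: str = "simulate"  # "simulate" | "load"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    manifest_path: str | None = None
    metadata_path: str | None = None
    labels_path: str | None = None
    fn_thresholds: tuple[int, ...] = (1, 2, 3, 4, 5)
    primary_fn: int = 3
    null_m: int = 100
    swap_factor: float = 10.0
    alpha: float = 0.05
    hub_top_fraction: float = 0.2
    hub_score_threshold: int = 2
    out_dir: str = "wmnet_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        if self.primary_fn not in self.fn_thresholds:
            raise ValueError("primary_fn must be one of fn_thresholds")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode == "load" and not (self.manifest_path and self.metadata_path):
            raise ValueError("load mode requires manifest_path and metadata_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        cfg = cls(cohort=cohort, **raw)
        if isinstance(cfg.fn_thresholds, list):
            cfg.fn_thresholds = tuple(cfg.fn_thresholds)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["fn_thresholds"] = list(self.fn_thresholds)
        d["cohort"]["planted_hub_nodes"] = list(self.cohort.planted_hub_nodes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        """Fingerprint of the scientifically relevant configuration."""
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    global_by_threshold: pd.DataFrame
    global_primary: pd.DataFrame
    nodal_tables: dict[str, pd.DataFrame]
    hub_tables: dict[str, pd.DataFrame]
    hub_comparison: object
    report: object
    summary: dict
    out_dir: Path


def _global_with_nulls(net: BinaryNetwork, m: int, swap_factor: float, seed: int) -> GlobalMetrics:
    dm = shortest_paths(net)
    _, cp = clustering(net)
    _, lp, frac = characteristic_path_length(dm)
    _, ge = global_efficiency(dm)
    _, loce = local_efficiency(net)
    gm = GlobalMetrics(cp=cp, lp=lp, loce=loce, ge=ge, disconnected_pair_fraction=frac)
    if m > 0:
        ens = build_ensemble(net, m=m, swap_factor=swap_factor, seed=seed)
        nm = normalized_metrics(net, ens, cp_real=cp, lp_real=lp)
        gm.gamma, gm.lam, gm.sigma = nm.gamma, nm.lam, nm.sigma
    return gm


def _acquire(config: RunConfig) -> tuple[dict[str, ConnectivityCountMatrix], pd.DataFrame]:
    if config.mode == "simulate":
        cohort_cfg = config.cohort
        log.info(
            "simulating cohort: %d controls, %d patients, seed %d",
            cohort_cfg.n_controls, cohort_cfg.n_patients, cohort_cfg.seed,
        )
        return generate_cohort(cohort_cfg)
    manifest = wio.read_manifest(config.manifest_path)
    base = Path(config.manifest_path).parent
    matrices = {}
    for sid, p in manifest.items():
        p = Path(p)
        matrices[sid] = wio.load_count_matrix(p if p.is_absolute() else base / p)
    table = wio.load_cohort_table(config.metadata_path)
    missing = set(table["subject_id"]) ^ set(matrices)
    if missing:
        raise ValueError(f"manifest/metadata subject mismatch: {sorted(missing)}")
    return matrices, table


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and write the report tables under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    t0 = time.time()
    try:
        log.info("run config digest %s, seed %d", config.digest(), config.seed)
        matrices, cohort = _acquire(config)
        subjects = list(matrices)
        n_nodes = matrices[subjects[0]].n_nodes

        labels_df = wio.load_node_labels(config.labels_path)
        if len(labels_df) != n_nodes:
            raise ValueError(
                f"label table has {len(labels_df)} rows but matrices have "
                f"{n_nodes} nodes; supply a matching labels table"
            )
        labels = list(labels_df["abbreviation"])

        master = np.random.default_rng(config.seed)
        null_seeds = master.integers(
            0, 2**31 - 1, size=(len(subjects), len(config.fn_thresholds))
        )

        rows = []
        nodal_tables: dict[str, pd.DataFrame] = {}
        global_primary_rows = {}
        for si, sid in enumerate(subjects):
            try:
                nets = sweep_thresholds(
                    matrices[sid], config.fn_thresholds, node_labels=labels
                )
                for fi, fn in enumerate(config.fn_thresholds):
                    if fn == config.primary_fn:
                        ens = build_ensemble(
                            nets[fn],
                            m=config.null_m,
                            swap_factor=config.swap_factor,
                            seed=int(null_seeds[si, fi]),
                        ) if config.null_m > 0 else None
                        gm, nodal = compute_all(nets[fn], nulls=ens)
                        nodal_tables[sid] = nodal
                        global_primary_rows[sid] = gm.as_dict()
                    else:
                        gm = _global_with_nulls(
                            nets[fn],
                            config.null_m,
                            config.swap_factor,
                            int(null_seeds[si, fi]),
                        )
                    rows.append({"subject_id": sid, "fn": fn, **gm.as_dict()})
            except Exception as e:
                raise RuntimeError(f"metrics stage failed for subject {sid}: {e}") from e
            if (si + 1) % 25 == 0:
                log.info("metrics: %d/%d subjects done", si + 1, len(subjects))

        global_by_threshold = pd.DataFrame(rows)
        global_primary = pd.DataFrame.from_dict(global_primary_rows, orient="index")
        global_primary.index.name = "subject_id"

        # group statistics at the primary threshold
        report = run_group_analysis(
            global_primary,
            nodal_tables,
            cohort,
            alpha=config.alpha,
            node_labels=labels,
        )

        # hub analysis from subject-averaged nodal metrics, per group
        cohort_idx = cohort.set_index("subject_id")
        hub_tables = {}
        for grp in ["HC", "SSNHL"]:
            members = [s for s in subjects if cohort_idx.loc[s, "group"] == grp]
            if not members:
                continue
            gm_nodal = group_nodal_means([nodal_tables[s] for s in members])
            hub_tables[grp] = hubness_scores(
                gm_nodal,
                top_fraction=config.hub_top_fraction,
                score_threshold=config.hub_score_threshold,
            )
        comparison = (
            compare_hubs(hub_tables["HC"], hub_tables["SSNHL"])
            if len(hub_tables) == 2
            else None
        )

        # group-mean sigma per (group, fn) for the threshold-sweep summary
        merged = global_by_threshold.merge(
            cohort[["subject_id", "group"]], on="subject_id"
        )
        sigma_sweep = (
            merged.groupby(["group", "fn"])["sigma"].mean().unstack().round(4)
            if config.null_m > 0
            else None
        )

        summary = {
            "seed": config.seed,
            "config_digest": config.digest(),
            "n_subjects": len(subjects),
            "n_nodes": n_nodes,
            "fn_thresholds": list(config.fn_thresholds),
            "primary_fn": config.primary_fn,
            "null_ensemble_m": config.null_m,
            "group_mean_sigma_by_fn": (
                {g: sigma_sweep.loc[g].to_dict() for g in sigma_sweep.index}
                if sigma_sweep is not None
                else None
            ),
            "n_hubs": {g: int(t["is_hub"].sum()) for g, t in hub_tables.items()},
            "shared_hubs": sorted(comparison.shared) if comparison else None,
            "hubs_specific_HC": sorted(comparison.specific_group1) if comparison else None,
            "hubs_specific_SSNHL": sorted(comparison.specific_group2) if comparison else None,
            "flagged_global_parameters": report.flagged_global,
            "elapsed_s": round(time.time() - t0, 2),
        }

        # write artifacts
        global_by_threshold.to_csv(out / "global_by_threshold.tsv", sep="\t", index=False)
        global_primary.to_csv(out / "global_primary.tsv", sep="\t")
        report.demographics.to_csv(out / "demographics.tsv", sep="\t", index=False)
        report.global_comparison.to_csv(out / "global_comparison.tsv", sep="\t", index=False)
        report.nodal_comparison.to_csv(out / "nodal_comparison.tsv", sep="\t", index=False)
        report.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
        for grp, t in hub_tables.items():
            t.to_csv(out / f"hubs_{grp}.tsv", sep="\t")
        config.to_yaml(out / "config.yaml")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        log.info("pipeline finished in %.1f s; outputs in %s", time.time() - t0, out)

        return PipelineResult(
            global_by_threshold=global_by_threshold,
            global_primary=global_primary,
            nodal_tables=nodal_tables,
            hub_tables=hub_tables,
            hub_comparison=comparison,
            report=report,
            summary=summary,
            out_dir=out,
        )
    finally:
        log.removeHandler(fh)
        fh.close()


def simulate_to_disk(cohort_cfg: CohortConfig, out_dir: str | Path) -> Path:
    """Write a simulated cohort as matrix files + metadata CSV + manifest."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    matrices, table = generate_cohort(cohort_cfg)
    mapping = {}
    for sid, cm in matrices.items():
        rel = f"matrices/{sid}.txt"
        wio.save_count_matrix(cm, out / rel)
        mapping[sid] = rel
    wio.write_manifest(mapping, out / "manifest.tsv")
    wio.save_cohort_table(table, out / "metadata.csv")
    return out
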