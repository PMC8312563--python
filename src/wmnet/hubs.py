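"""Hub identification by the four-criterion nodal ranking.

A node earns one point per criterion met: top 20% highest degree (Di),
top 20% highest betweenness (Bi), bottom 20% lowest nodal clustering,
bottom 20% lowest nodal path length.  The hubness score therefore ranges
0-4, and nodes scoring at least 2 are classified as putative hubs.
Group-level hub tables are computed from subject-averaged nodal metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HubComparison", "hubness_scores", "group_nodal_means", "compare_hubs"]

HUB_SCORE_THRESHOLD = 2
CRITERIA = ("high_degree", "high_betweenness", "low_clustering", "low_path_length")


def _top_k(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values; ties broken by lower node index."""
    order = np.lexsort((np.arange(values.size), -values))
    return order[:k]


def _bottom_k(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest values; NaN ranks last; ties by lower index."""
    v = np.where(np.isnan(values), np.inf, values)
    order = np.lexsort((np.arange(v.size), v))
    return order[:k]


def hubness_scores(
    nodal: pd.DataFrame,
    top_fraction: float = 0.2,
    score_threshold: int = HUB_SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Score each node on the four rank criteria and flag hubs.

    ``nodal`` must carry columns ``degree``, ``betweenness``,
    ``clustering`` and ``path_length`` (one row per node); a ``label``
    column, if present, is carried through.  k = ceil(top_fraction * n)
    nodes are selected per criterion.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    n = len(nodal)
    k = math.ceil(top_fraction * n)
    flags = pd.DataFrame(False, index=nodal.index, columns=list(CRITERIA))
    pos = {
        "high_degree": _top_k(nodal["degree"].to_numpy(dtype=float), k),
        "high_betweenness": _top_k(nodal["betweenness"].to_numpy(dtype=float), k),
        "low_clustering": _bottom_k(nodal["clustering"].to_numpy(dtype=float), k),
        "low_path_length": _bottom_k(nodal["path_length"].to_numpy(dtype=float), k),
    }
    for crit, idx in pos.items():
        flags.iloc[idx, flags.columns.get_loc(crit)] = True
    out = flags.copy()
    out.insert(0, "score", flags.sum(axis=1).astype(int))
    out["is_hub"] = out["score"] >= score_threshold
    if "label" in nodal.columns:
        out.insert(0, "label", nodal["label"])
    out.index.name = "node"
    return out


def group_nodal_means(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of nodal metrics across subjects.

    Undefined (NaN) nodal path lengths are excluded from that node's
    mean; the number excluded is reported in ``path_length_n_undefined``.
    """
    if not tables:
        raise ValueError("need at least one subject table")
    n = len(tables[0])
    if any(len(t) != n for t in tables):
        raise ValueError("inconsistent node count across subjects")
    metric_cols = [c for c in tables[0].columns if c != "label"]
    stacked = pd.concat([t[metric_cols] for t in tables], keys=range(len(tables)))
    mean = stacked.groupby(level=1).mean()
    mean["path_length_n_undefined"] = (
        stacked["path_length"].isna().groupby(level=1).sum().astype(int)
    )
    if "label" in tables[0].columns:
        mean.insert(0, "label", tables[0]["label"].to_numpy())
    mean.index.name = "node"
    return mean


@dataclass
class HubComparison:
    shared: frozenset
    specific_group1: frozenset
    specific_group2: frozenset


def _hub_ids(table: pd.DataFrame):
    ids = table.index[table["is_hub"]]
    if "label" in table.columns:
        return frozenset(table.loc[ids, "label"])
    return frozenset(ids)


def compare_hubs(table1: pd.DataFrame, table2: pd.DataFrame) -> HubComparison:
    """Shared and group-specific hub sets from two hub tables."""
    if len(table1) != len(table2) or not table1.index.equals(table2.index):
        raise ValueError("hub tables must cover the same node set")
    if "label" in table1.columns and "label" in table2.columns:
        if not (table1["label"].to_numpy() == table2["label"].to_numpy()).all():
            raise ValueError("hub tables must cover the same node set (labels differ)")
    h1, h2 = _hub_ids(table1), _hub_ids(table2)
    return HubComparison(
        shared=h1 & h2, specific_group1=h1 - h2, specific_group2=h2 - h1
    )
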