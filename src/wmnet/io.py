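"""Plain-text I/O: count matrices, node labels, cohort tables, manifests."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .construction import ConnectivityCountMatrix

__all__ = [
    "load_count_matrix",
    "save_count_matrix",
    "load_node_labels",
    "load_cohort_table",
    "save_cohort_table",
    "read_manifest",
    "write_manifest",
]


def load_count_matrix(path: str | Path) -> ConnectivityCountMatrix:
    """Read a whitespace- or comma-delimited square count matrix.

    Validates the connectivity-matrix invariants (square, symmetric,
    integer, non-negative, zero diagonal) and raises a named error on
    the first violation.  The subject id defaults to the file stem.
    """
    path = Path(path)
    text = path.read_text()
    delim = "," if "," in text.splitlines()[0] else None
    try:
        m = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as e:
        raise ValueError(f"{path}: not a numeric matrix ({e})") from None
    try:
        return ConnectivityCountMatrix(m, subject_id=path.stem)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def save_count_matrix(cm: ConnectivityCountMatrix, path: str | Path) -> None:
    np.savetxt(path, cm.counts, fmt="%d", delimiter="\t")


def load_node_labels(path: str | Path | None = None) -> pd.DataFrame:
    """Node label table (index, abbreviation, name, class).

    Without a path, the packaged AAL-90 table is returned.
    """
    if path is None:
        ref = resources.files("wmnet.data") / "aal90_labels.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age", "gender", "education"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: cohort table missing columns {sorted(missing)}")
    return df


def save_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_manifest(mapping: dict[str, str], path: str | Path) -> None:
    """subject_id -> matrix file path, tab-separated with header."""
    pd.DataFrame(
        {"subject_id": list(mapping), "path": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["subject_id"].astype(str), df["path"].astype(str)))
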