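"""Reading and writing the pipeline's plain-text tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .effect_size import MEASUREMENT_COLUMNS

__all__ = [
    "read_measurements",
    "write_measurements",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_pcoa",
]


def read_measurements(path) -> pd.DataFrame:
    """Parse and validate a long-format measurement TSV.

    Expects the exact header ``sample_id treatment timepoint replicate
    variable value``; rejects duplicate (sample_id, variable) keys, missing
    fields, and non-finite values, naming the offending line or key.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols != list(MEASUREMENT_COLUMNS):
        raise ValueError(
            f"unknown or misordered columns {cols}; expected {list(MEASUREMENT_COLUMNS)}"
        )
    if df.empty:
        raise ValueError("empty data section")
    if df.isna().any(axis=None):
        line = int(df.index[df.isna().any(axis=1)][0]) + 2  # header is line 1
        raise ValueError(f"malformed row at line {line}: missing field")
    try:
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
    except ValueError as exc:
        raise ValueError(f"malformed numeric field: {exc}") from exc
    if not np.all(np.isfinite(df["value"])):
        line = int(df.index[~np.isfinite(df["value"])][0]) + 2
        raise ValueError(f"malformed row at line {line}: non-finite value")
    dup = df.duplicated(subset=["sample_id", "variable"])
    if dup.any():
        key = df.loc[dup, ["sample_id", "variable"]].iloc[0]
        raise ValueError(
            f"duplicate (sample_id, variable) key: ({key.sample_id!r}, {key.variable!r})"
        )
    return df


def write_measurements(measurements: pd.DataFrame, path) -> None:
    measurements.to_csv(path, sep="\t", index=False)


def write_distance_matrix(dm, path) -> None:
    """Square labelled TSV of a scikit-bio DistanceMatrix."""
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_distance_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_pcoa(coords: pd.DataFrame, eigenvalues: np.ndarray, path) -> None:
    """Coordinates TSV preceded by an eigenvalue header line."""
    with open(path, "w") as fh:
        fh.write("# eigenvalues\t" + "\t".join(f"{v:.6g}" for v in eigenvalues) + "\n")
        coords.to_csv(fh, sep="\t")
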