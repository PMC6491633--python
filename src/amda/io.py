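"""Readers and writers for TSV/CSV abundance tables and label files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mmd import GroupLabels
from .transforms import AbundanceTable

__all__ = ["read_abundance_table", "write_abundance_table", "read_labels",
           "write_labels"]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance_table(path, taxa_in: str = "columns") -> AbundanceTable:
    """Load a samples x taxa table from TSV/CSV.

    ``taxa_in="rows"`` accepts the common OTU-table convention (taxa as
    rows, samples as columns) and transposes on load.  The first column
    holds row identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if taxa_in == "rows":
        df = df.T
    elif taxa_in != "columns":
        raise ValueError("taxa_in must be 'rows' or 'columns'")
    return AbundanceTable(
        df.to_numpy(dtype=float),
        taxa_ids=tuple(str(c) for c in df.columns),
        sample_ids=tuple(str(i) for i in df.index),
    )


def write_abundance_table(table: AbundanceTable, path) -> Path:
    path = Path(path)
    pd.DataFrame(table.values, index=list(table.sample_ids),
                 columns=list(table.taxa_ids)).to_csv(path, sep=_sep(path))
    return path


def read_labels(path, sample_ids=None) -> GroupLabels:
    """Load group labels from TSV/CSV.

    Two-column files are read as (sample_id, group) and reordered to match
    ``sample_ids`` when given; single-column files are taken as already
    aligned with the table's row order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), header=None, comment="#")
    if df.shape[1] == 1:
        labels = df.iloc[:, 0]
        if not np.issubdtype(labels.dtype, np.number):  # header line
            df = pd.read_csv(path, sep=_sep(path), comment="#")
            labels = df.iloc[:, 0]
        return GroupLabels(labels.to_numpy(dtype=int))
    if not np.issubdtype(df.iloc[:, 1].dtype, np.number):  # header present
        df = pd.read_csv(path, sep=_sep(path), comment="#")
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))
    if sample_ids is not None:
        try:
            ordered = [mapping[str(s)] for s in sample_ids]
        except KeyError as exc:
            raise ValueError(f"label file is missing sample {exc}") from exc
        return GroupLabels(np.asarray(ordered))
    return GroupLabels(df.iloc[:, 1].to_numpy(dtype=int))


def write_labels(labels: GroupLabels, path, sample_ids=None) -> Path:
    path = Path(path)
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(labels.n)]
    pd.DataFrame({"sample_id": list(sample_ids),
                  "group": labels.labels}).to_csv(
        path, sep=_sep(path), index=False, header=False)
    return path
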