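"""Compositional normalization and the centered log-ratio (CLR) transform.

Microbiome read counts are compositional: only relative abundances are
comparable across samples.  The standard pipeline applied here is

1. ``replace_zeros`` — replace exact zeros by a pseudo count (default 0.5)
   so logarithms are defined,
2. ``to_composition`` — divide each sample (row) by its total so rows sum
   to one,
3. ``clr`` — log of each entry relative to the geometric mean of its row,
   mapping each composition onto a zero-sum real vector.

All functions accept either an :class:`AbundanceTable` / plain ``ndarray``
and return the matching kind.  Samples are rows, taxa are columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AbundanceTable",
    "ClrMatrix",
    "replace_zeros",
    "to_composition",
    "clr",
]

#: |row sum| tolerance for CLR output, relative to the row's max |entry|.
CLR_ROWSUM_RTOL = 1e-10


def _default_ids(prefix: str, k: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i}" for i in range(k))


@dataclass(frozen=True)
class AbundanceTable:
    """A samples x taxa matrix of nonnegative counts or relative abundances."""

    values: np.ndarray
    taxa_ids: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("abundance table must be 2-dimensional")
        n, p = v.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 samples and 2 taxa, got {v.shape}")
        if np.isnan(v).any():
            raise ValueError("abundance table contains NaN")
        if (v < 0).any():
            raise ValueError("abundance table contains negative entries")
        object.__setattr__(self, "values", v)
        taxa = tuple(self.taxa_ids) or _default_ids("taxon_", p)
        samples = tuple(self.sample_ids) or _default_ids("sample_", n)
        if len(taxa) != p:
            raise ValueError(f"{len(taxa)} taxa ids for {p} columns")
        if len(samples) != n:
            raise ValueError(f"{len(samples)} sample ids for {n} rows")
        if len(set(taxa)) != p or len(set(samples)) != n:
            raise ValueError("taxa and sample ids must be unique")
        object.__setattr__(self, "taxa_ids", taxa)
        object.__setattr__(self, "sample_ids", samples)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ClrMatrix:
    """CLR-transformed abundances; every row sums to zero."""

    values: np.ndarray
    taxa_ids: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("CLR matrix must be 2-dimensional")
        if not np.isfinite(v).all():
            raise ValueError("CLR matrix contains non-finite entries")
        rowsum = np.abs(v.sum(axis=1))
        scale = np.maximum(np.abs(v).max(axis=1), 1.0)
        if (rowsum > CLR_ROWSUM_RTOL * scale).any():
            raise ValueError("CLR rows must sum to zero")
        object.__setattr__(self, "values", v)
        n, p = v.shape
        taxa = tuple(self.taxa_ids) or _default_ids("taxon_", p)
        samples = tuple(self.sample_ids) or _default_ids("sample_", n)
        object.__setattr__(self, "taxa_ids", taxa)
        object.__setattr__(self, "sample_ids", samples)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


def _unwrap(table):
    if isinstance(table, (AbundanceTable, ClrMatrix)):
        return table.values, table
    v = np.asarray(table, dtype=float)
    return v, None


def replace_zeros(table, pseudo: float = 0.5):
    """Replace exact-zero entries by a pseudo count (default 0.5).

    Nonzero entries are left untouched.  This is the conventional guard
    against undefined log-ratios in sparse count tables.
    """
    if pseudo <= 0:
        raise ValueError("pseudo count must be positive")
    v, wrapper = _unwrap(table)
    if (v < 0).any():
        raise ValueError("abundances must be nonnegative")
    out = np.where(v == 0, float(pseudo), v)
    if wrapper is None:
        return out
    return AbundanceTable(out, wrapper.taxa_ids, wrapper.sample_ids)


def to_composition(table):
    """Normalize each row to relative abundances (row sums of one)."""
    v, wrapper = _unwrap(table)
    sums = v.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("every sample must have a positive total abundance")
    out = v / sums
    if wrapper is None:
        return out
    return AbundanceTable(out, wrapper.taxa_ids, wrapper.sample_ids)


def clr_values(values: np.ndarray) -> np.ndarray:
    """CLR transform on a raw array of strictly positive abundances."""
    v = np.asarray(values, dtype=float)
    if (v <= 0).any():
        raise ValueError(
            "CLR requires strictly positive entries; run replace_zeros and "
            "to_composition first"
        )
    logv = np.log(v)
    return logv - logv.mean(axis=1, keepdims=True)


def clr(table):
    """Centered log-ratio transform: log(x_ij / geometric_mean(row i)).

    Equivalent to subtracting the row mean of the logged entries, so every
    output row sums to zero and the result is invariant to per-sample
    rescaling (in particular to whether ``to_composition`` was applied).
    """
    v, wrapper = _unwrap(table)
    out = clr_values(v)
    if wrapper is None:
        return out
    return ClrMatrix(out, wrapper.taxa_ids, wrapper.sample_ids)
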