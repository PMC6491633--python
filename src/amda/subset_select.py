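"""Permutation-based selection of the testing subset of taxa.

The adaptive test does not screen taxa against a fixed significance cutoff.
Instead it builds a *decoy*: a copy of the CLR matrix whose rows are jointly
re-ordered by one random permutation, which breaks any row-label association
while preserving every pooled column distribution exactly.  Each taxon j
then receives two marginal two-sample KS p-values — p_j on the real matrix
and p̃_j on the decoy — and the testing subset is

    S = { j : p_j < p̃_j }   (strict; ties are not selected).

For a truly differential taxon p_j is stochastically smaller than p̃_j, so S
tends to capture signal columns, while under the null each column is
selected with probability about one half.  Because the same construction is
repeated inside every outer label permutation, the selection step does not
break the exchangeability on which the permutation p-value rests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._ks import ks_pvalues_from_d_int
from .mmd import GroupLabels, as_group_labels
from .transforms import ClrMatrix

__all__ = ["SubsetSelection", "make_decoy", "marginal_pvalues", "select_subset"]


@dataclass(frozen=True)
class SubsetSelection:
    """Result of one decoy-based selection round."""

    selected: tuple[int, ...]
    pvals_real: np.ndarray
    pvals_decoy: np.ndarray
    decoy_seed: int | None
    decoy_permutation: np.ndarray = field(repr=False, default=None)

    @property
    def size(self) -> int:
        return len(self.selected)


def _values(Z) -> np.ndarray:
    if isinstance(Z, ClrMatrix):
        return Z.values
    return np.asarray(Z, dtype=float)


def _as_rng(seed):
    if hasattr(seed, "permutation"):
        return seed
    return np.random.default_rng(seed)


def make_decoy(Z, rng) -> np.ndarray | ClrMatrix:
    """Row-permute Z by one uniformly random permutation.

    Rows stay intact (the multiset of samples is unchanged); only their
    pairing with the group labels is destroyed.
    """
    rng = _as_rng(rng)
    v = _values(Z)
    perm = rng.permutation(v.shape[0])
    out = v[perm]
    if isinstance(Z, ClrMatrix):
        return ClrMatrix(out, Z.taxa_ids, tuple(np.asarray(Z.sample_ids)[perm]))
    return out


def column_d_ints(Z, y) -> np.ndarray:
    """Lattice KS statistics max|i*n2 - j*n1| for every column of Z.

    Vectorized over columns: each column is argsorted once, group weights
    (+n2 for group 1, -n1 for group 2) are gathered in sorted order and
    cumulatively summed; the ECDF gap is read off at the end of each run of
    tied values.
    """
    v = _values(Z)
    labels = as_group_labels(y)
    n1, n2 = labels.n1, labels.n2
    order = np.argsort(v, axis=0, kind="stable")
    w = np.where(labels.labels == 1, n2, -n1).astype(np.int64)
    cum = np.cumsum(w[order], axis=0)
    vs = np.take_along_axis(v, order, 0)
    valid = np.ones_like(v, dtype=bool)
    valid[:-1] = vs[:-1] != vs[1:]
    return np.abs(np.where(valid, cum, 0)).max(axis=0).astype(np.int64)


def marginal_pvalues(Z, y, mode: str = "auto") -> np.ndarray:
    """Two-sided two-sample KS p-value for each taxon column.

    mode "auto" uses the exact small-sample null when n1*n2 <= 10^4 and the
    asymptotic formula otherwise.  A column that is constant across all
    samples has KS statistic 0 and p-value 1.
    """
    labels = as_group_labels(y)
    d = column_d_ints(Z, labels)
    return ks_pvalues_from_d_int(d, labels.n1, labels.n2, mode=mode)


def select_subset(Z, y, rng, mode: str = "auto") -> SubsetSelection:
    """One round of decoy-based testing-subset selection.

    Draws a single decoy permutation from ``rng`` (an int seed or a
    ``numpy.random.Generator``), computes marginal KS p-values on the real
    and decoy matrices with the *same* p-value mode, and keeps the columns
    where the real p-value is strictly smaller.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = _as_rng(rng)
    labels = as_group_labels(y)
    v = _values(Z)
    perm = gen.permutation(v.shape[0])
    p_real = marginal_pvalues(v, labels, mode=mode)
    p_decoy = marginal_pvalues(v[perm], labels, mode=mode)
    selected = tuple(int(j) for j in np.flatnonzero(p_real < p_decoy))
    return SubsetSelection(
        selected=selected,
        pvals_real=p_real,
        pvals_decoy=p_decoy,
        decoy_seed=int(seed) if seed is not None else None,
        decoy_permutation=perm,
    )
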