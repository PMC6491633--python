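"""The squared maximum mean discrepancy (MMD^2) two-sample statistic.

``mmd2`` implements the biased V-statistic estimator

    MMD^2 = 1/n1^2 sum_{i,j in G1} K_ij + 1/n2^2 sum_{i,j in G2} K_ij
            - 2/(n1 n2) sum_{i in G1, j in G2} K_ij

with all index pairs (diagonals included), which is nonnegative for a
positive-semidefinite kernel.  The unbiased U-statistic variant (diagonal
terms removed) is available via ``unbiased=True`` but is not used by the
permutation tests in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GroupLabels", "mmd2"]


@dataclass(frozen=True)
class GroupLabels:
    """Two-group assignment: a length-n vector over {1, 2}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 1:
            raise ValueError("labels must be a 1-d vector")
        lab = lab.astype(np.int64)
        if not np.isin(lab, (1, 2)).all():
            raise ValueError("labels must take values in {1, 2}")
        if (lab == 1).sum() < 1 or (lab == 2).sum() < 1:
            raise ValueError("both groups must be nonempty")
        object.__setattr__(self, "labels", lab)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def n1(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n2(self) -> int:
        return int((self.labels == 2).sum())

    def require_min_group_size(self, k: int = 2) -> None:
        if self.n1 < k or self.n2 < k:
            raise ValueError(f"each group needs at least {k} samples "
                             f"(got n1={self.n1}, n2={self.n2})")


def as_group_labels(y) -> GroupLabels:
    if isinstance(y, GroupLabels):
        return y
    return GroupLabels(np.asarray(y))


def mmd2(K: np.ndarray, y, unbiased: bool = False) -> float:
    """Squared MMD from a precomputed kernel matrix and group labels.

    Computed as v'Kv with v_i = 1/n1 for group 1 and -1/n2 for group 2,
    which expands exactly to the three-block double sum above.
    """
    labels = as_group_labels(y)
    K = np.asarray(K, dtype=float)
    n = labels.n
    if K.shape != (n, n):
        raise ValueError(f"kernel matrix shape {K.shape} does not match n={n}")
    g1 = labels.labels == 1
    n1, n2 = labels.n1, labels.n2
    if unbiased:
        if n1 < 2 or n2 < 2:
            raise ValueError("unbiased MMD^2 needs at least 2 samples per group")
        K11 = K[np.ix_(g1, g1)]
        K22 = K[np.ix_(~g1, ~g1)]
        K12 = K[np.ix_(g1, ~g1)]
        t11 = (K11.sum() - np.trace(K11)) / (n1 * (n1 - 1))
        t22 = (K22.sum() - np.trace(K22)) / (n2 * (n2 - 1))
        t12 = 2.0 * K12.sum() / (n1 * n2)
        return float(t11 + t22 - t12)
    v = np.where(g1, 1.0 / n1, -1.0 / n2)
    return float(v @ K @ v)
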