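"""Gaussian kernel matrices with the median-heuristic shape parameter.

The kernel used throughout is ``k(x, y) = exp(-||x - y||^2 / rho)`` with
``rho`` set, by default, to the median of the squared pairwise Euclidean
distances between samples (the "median heuristic").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .transforms import ClrMatrix

__all__ = ["KernelSpec", "median_heuristic", "gram"]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus shape parameter; ``rho='median'`` defers to the data."""

    name: str = "gaussian"
    rho: float | str = "median"

    def __post_init__(self) -> None:
        if self.name != "gaussian":
            raise ValueError(f"unsupported kernel {self.name!r}")
        if isinstance(self.rho, str):
            if self.rho != "median":
                raise ValueError("rho must be a positive number or 'median'")
        elif self.rho <= 0:
            raise ValueError("rho must be positive")

    def resolve(self, Z) -> "KernelSpec":
        """Return a copy with a numeric rho (median heuristic if deferred)."""
        if isinstance(self.rho, str):
            return KernelSpec(self.name, median_heuristic(Z))
        return self


def _values(Z) -> np.ndarray:
    if isinstance(Z, ClrMatrix):
        return Z.values
    return np.asarray(Z, dtype=float)


def median_heuristic(Z, squared: bool = True) -> float:
    """Median of pairwise Euclidean distances between rows of Z.

    By default the median of *squared* distances over the n(n-1)/2 unordered
    distinct pairs (self-pairs excluded).  ``squared=False`` gives the median
    of unsquared distances for sensitivity checks.

    Raises if all rows coincide: a zero bandwidth is meaningless and such
    data cannot carry a two-sample signal.
    """
    v = _values(Z)
    if v.shape[0] < 2:
        raise ValueError("need at least two samples")
    d = pdist(v, metric="sqeuclidean" if squared else "euclidean")
    med = float(np.median(d))
    if med <= 0:
        raise ValueError("median pairwise distance is zero (all rows identical)")
    return med


def gram(Z, spec: KernelSpec | None = None) -> np.ndarray:
    """Gaussian Gram matrix K[i, j] = exp(-||Z_i - Z_j||^2 / rho)."""
    if spec is None:
        spec = KernelSpec()
    spec = spec.resolve(Z)
    v = _values(Z)
    d2 = squareform(pdist(v, metric="sqeuclidean"))
    return np.exp(-d2 / spec.rho)
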