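"""Logistic-normal simulator for type-I-error and power studies.

Each replicate draws latent Gaussian vectors W_i ~ N_p(mu^(k), Sigma) per
group and maps them to compositions by the softmax X_ij = exp(W_ij) /
sum_j exp(W_ij), i.e. relative abundances from a logistic-normal
distribution.  The design emulates a correlated taxa community:

* baseline log-abundances mu^(1) with components drawn Unif(0, 10);
* banded covariance Sigma = D^{1/2} A D^{1/2} with D diagonal Unif(1, 3)
  and A tridiagonal (1 on the diagonal, -0.5 on the first off-diagonals),
  giving strong negative neighbor correlation (A is positive definite for
  every p: its eigenvalues are 1 - cos(k*pi/(p+1)) > 0);
* under the null mu^(2) = mu^(1); under the alternative a random signal
  subset S of round(sparsity * p) taxa receives mean shifts e_j drawn
  Unif(-0.5, 0.5), all other components equal.

mu^(1), D and S are re-drawn for every replicate (each dataset is a fresh
draw of the whole design), and a fixed scenario seed reproduces the
dataset bit for bit.  Softmax output has no zeros, so the pseudo-count
stage of the analysis pipeline is a no-op on simulated data; it remains in
the pipeline for interface fidelity with real count tables.

A useful algebraic identity couples this module to the transforms: the CLR
of a softmax is the centered latent vector, clr(softmax(w)) = w - mean(w).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mmd import GroupLabels
from .transforms import AbundanceTable

__all__ = [
    "SimulationScenario",
    "ScenarioTruth",
    "build_covariance",
    "draw_means",
    "generate_dataset",
]

_chol_cache: dict[int, np.ndarray] = {}


def _banded_cholesky(p: int) -> np.ndarray:
    """Lower Cholesky factor of the tridiagonal correlation matrix A."""
    if p not in _chol_cache:
        A = np.eye(p) + np.diag(np.full(p - 1, -0.5), 1) + np.diag(np.full(p - 1, -0.5), -1)
        _chol_cache[p] = np.linalg.cholesky(A)
    return _chol_cache[p]


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation grid."""

    p: int
    n: int
    sparsity: float = 0.3
    effect_low: float = -0.5
    effect_high: float = 0.5
    seed: int | None = 0
    null_model: bool = False

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError("need at least 2 taxa")
        if self.n % 2 != 0 or self.n < 4:
            raise ValueError("n must be even and at least 4 (two groups of >= 2)")
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must be in (0, 1]")

    def with_seed(self, seed) -> "SimulationScenario":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth behind one simulated dataset."""

    mu1: np.ndarray
    mu2: np.ndarray
    Sigma: np.ndarray
    signal_set: tuple[int, ...]


def build_covariance(p: int, rng) -> np.ndarray:
    """Banded covariance D^{1/2} A D^{1/2} with D ~ Unif(1, 3) diagonal."""
    if p < 2:
        raise ValueError("need p >= 2")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    d = rng.uniform(1.0, 3.0, size=p)
    A = np.eye(p) + np.diag(np.full(p - 1, -0.5), 1) + np.diag(np.full(p - 1, -0.5), -1)
    s = np.sqrt(d)
    return s[:, None] * A * s[None, :]


def draw_means(
    p: int,
    sparsity: float,
    null_model: bool,
    rng,
    effect_low: float = -0.5,
    effect_high: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Group means mu^(1), mu^(2) and the signal subset."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mu1 = rng.uniform(0.0, 10.0, size=p)
    if null_model:
        return mu1, mu1.copy(), ()
    k = int(round(sparsity * p))
    signal = np.sort(rng.choice(p, size=k, replace=False))
    mu2 = mu1.copy()
    mu2[signal] += rng.uniform(effect_low, effect_high, size=k)
    return mu1, mu2, tuple(int(j) for j in signal)


def generate_dataset(
    scenario: SimulationScenario,
) -> tuple[AbundanceTable, GroupLabels, ScenarioTruth]:
    """One simulated dataset: n/2 samples per group, rows summing to one."""
    rng = np.random.default_rng(scenario.seed)
    p, n = scenario.p, scenario.n
    mu1, mu2, signal = draw_means(
        p, scenario.sparsity, scenario.null_model, rng,
        scenario.effect_low, scenario.effect_high,
    )
    d = rng.uniform(1.0, 3.0, size=p)
    s = np.sqrt(d)
    L = _banded_cholesky(p)
    A = np.eye(p) + np.diag(np.full(p - 1, -0.5), 1) + np.diag(np.full(p - 1, -0.5), -1)
    Sigma = s[:, None] * A * s[None, :]

    half = n // 2
    xi = rng.standard_normal((n, p))
    latent = (xi @ L.T) * s[None, :]  # rows ~ N_p(0, Sigma)
    W = latent + np.vstack([np.tile(mu1, (half, 1)), np.tile(mu2, (half, 1))])

    expw = np.exp(W - W.max(axis=1, keepdims=True))  # stable softmax
    X = expw / expw.sum(axis=1, keepdims=True)

    table = AbundanceTable(X)
    labels = GroupLabels(np.repeat([1, 2], half))
    truth = ScenarioTruth(mu1=mu1, mu2=mu2, Sigma=Sigma, signal_set=signal)
    return table, labels, truth
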