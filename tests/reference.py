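"""Independent brute-force oracles for the test suite.

Everything here is written as literally as possible — per-column scipy KS
calls, explicit double-sum MMD, one permutation at a time — and stays
independent of the package's vectorized engine.  The only shared piece is
the RNG stream protocol (master seed -> permutation/decoy child streams),
which is part of the public reproducibility contract.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from amda.adaptive import spawn_streams
from amda.transforms import clr, replace_zeros, to_composition


def clr_reference(row: np.ndarray) -> np.ndarray:
    gm = math.exp(sum(math.log(v) for v in row) / len(row))
    return np.array([math.log(v / gm) for v in row])


def median_heuristic_reference(Z: np.ndarray, squared: bool = True) -> float:
    n = Z.shape[0]
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            d2 = float(((Z[i] - Z[j]) ** 2).sum())
            dists.append(d2 if squared else math.sqrt(d2))
    return float(np.median(dists))


def gram_reference(Z: np.ndarray, rho: float) -> np.ndarray:
    n = Z.shape[0]
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = math.exp(-float(((Z[i] - Z[j]) ** 2).sum()) / rho)
    return K


def mmd2_reference(K: np.ndarray, y: np.ndarray) -> float:
    """Literal three-term double sum, all index pairs included."""
    idx1 = np.flatnonzero(y == 1)
    idx2 = np.flatnonzero(y == 2)
    n1, n2 = len(idx1), len(idx2)
    t11 = sum(K[i, j] for i in idx1 for j in idx1) / n1**2
    t22 = sum(K[i, j] for i in idx2 for j in idx2) / n2**2
    t12 = sum(K[i, j] for i in idx1 for j in idx2) / (n1 * n2)
    return t11 + t22 - 2.0 * t12


def ks_pvalues_reference(Z: np.ndarray, y: np.ndarray, mode: str) -> np.ndarray:
    x1 = Z[y == 1]
    x2 = Z[y == 2]
    out = []
    for j in range(Z.shape[1]):
        if np.all(Z[:, j] == Z[0, j]):
            out.append(1.0)
        else:
            out.append(stats.ks_2samp(x1[:, j], x2[:, j], method=mode).pvalue)
    return np.asarray(out)


def _selection_reference(Z, y, pi, mode):
    decoy = Z[pi]
    p_real = ks_pvalues_reference(Z, y, mode)
    p_decoy = ks_pvalues_reference(decoy, y, mode)
    return np.flatnonzero(p_real < p_decoy), p_real, p_decoy


def _subset_statistic_reference(Z, y, subset):
    if len(subset) == 0:
        return 0.0
    Zs = Z[:, subset]
    rho = median_heuristic_reference(Zs)
    K = gram_reference(Zs, rho)
    return mmd2_reference(K, y)


def amda_reference(table_values, y, B, seed, ks_mode="exact",
                   reselect=True):
    """Step-by-step adaptive test; returns (stat, pv, selected, perm_stats)."""
    Z = clr(to_composition(replace_zeros(np.asarray(table_values, float))))
    y = np.asarray(y)
    perm_rng, decoy_rng = spawn_streams(seed)

    pi_obs = decoy_rng.permutation(len(y))
    S_obs, p_real, p_decoy = _selection_reference(Z, y, pi_obs, ks_mode)
    stat_obs = _subset_statistic_reference(Z, y, S_obs)

    perm_stats = []
    for _ in range(B):
        y_b = y[perm_rng.permutation(len(y))]
        pi_b = decoy_rng.permutation(len(y))
        if reselect:
            S_b, _, _ = _selection_reference(Z, y_b, pi_b, ks_mode)
        else:
            S_b = S_obs
        perm_stats.append(_subset_statistic_reference(Z, y_b, S_b))
    perm_stats = np.asarray(perm_stats)
    pv = float((perm_stats >= stat_obs).mean())
    return stat_obs, pv, S_obs, perm_stats


def mmd_reference(table_values, y, B, seed, transform="composition"):
    comp = to_composition(replace_zeros(np.asarray(table_values, float)))
    Z = clr(comp) if transform == "clr" else comp
    y = np.asarray(y)
    perm_rng, _ = spawn_streams(seed)
    rho = median_heuristic_reference(Z)
    K = gram_reference(Z, rho)
    stat_obs = mmd2_reference(K, y)
    perm_stats = np.asarray([
        mmd2_reference(K, y[perm_rng.permutation(len(y))]) for _ in range(B)
    ])
    return stat_obs, float((perm_stats >= stat_obs).mean()), perm_stats


def max_statistic_reference(Z: np.ndarray, y: np.ndarray) -> float:
    """Per-column scan of the standardized squared mean difference."""
    idx1 = y == 1
    idx2 = y == 2
    n1, n2 = idx1.sum(), idx2.sum()
    best = 0.0
    for j in range(Z.shape[1]):
        a, b = Z[idx1, j], Z[idx2, j]
        denom = a.var(ddof=1) / n1 + b.var(ddof=1) / n2
        if denom > 0:
            best = max(best, (a.mean() - b.mean()) ** 2 / denom)
    return best
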