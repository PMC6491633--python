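"""Batched permutation engines for the adaptive, MMD and MAX tests.

The outer permutation loop dominates the cost of every test here (B label
permutations, each of which repeats subset selection for the adaptive
test), so the loop is executed in batched array form:

* KS lattice statistics for all permutations and all columns come from one
  pass over the column-sorted data (a numba kernel when available, a
  chunked numpy gather/cumsum otherwise).  A row-permuted decoy matrix
  split by labels y is equivalent to the original matrix split by the
  inverse-permuted labels, so decoy columns are never re-sorted.
* Subset distance matrices for all permutations come from a single matrix
  product of the per-column squared-difference stack (upper triangle only)
  with the 0/1 selection masks.
* MMD^2 = v'Kv with v = 1/n1 on group 1 and -1/n2 on group 2 reduces, for
  a unit-diagonal kernel, to (1/n1 + 1/n2) + 2 * sum_{i<j} v_i v_j K_ij.

Agreement with the literal one-permutation-at-a-time procedure is asserted
by the test suite against an independent reference implementation.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._ks import ks_pvalues_from_d_int, default_mode

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

#: cap for a MAX-test column with zero within-group variances but unequal
#: means (an infinite standardized difference; any permutation comparison
#: only needs a value larger than every finite column).
MAX_STAT_CAP = 1e12


# ---------------------------------------------------------------------------
# batched KS lattice statistics


def _ks_d_batch_numpy(order: np.ndarray, valid: np.ndarray, W: np.ndarray) -> np.ndarray:
    n, p = order.shape
    m = W.shape[0]
    out = np.empty((m, p), dtype=np.int64)
    chunk = max(1, int(4_000_000 // max(n * p, 1)))
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        g = W[lo:hi][:, order]           # (c, n, p)
        np.cumsum(g, axis=1, out=g)
        np.abs(g, out=g)
        g *= valid[None, :, :]
        out[lo:hi] = g.max(axis=1)
    return out


if _HAVE_NUMBA:

    @njit(cache=True)
    def _ks_d_batch_nb(order, valid, W):  # pragma: no cover - numba
        n, p = order.shape
        m = W.shape[0]
        out = np.empty((m, p), dtype=np.int64)
        col = np.empty(n, dtype=np.int64)
        ok = np.empty(n, dtype=np.bool_)
        for j in range(p):
            for k in range(n):
                col[k] = order[k, j]
                ok[k] = valid[k, j]
            for b in range(m):
                c = 0
                best = 0
                for k in range(n):
                    c += W[b, col[k]]
                    if ok[k]:
                        a = c if c >= 0 else -c
                        if a > best:
                            best = a
                out[b, j] = best
        return out


def ks_d_batch(order: np.ndarray, valid: np.ndarray, W: np.ndarray) -> np.ndarray:
    """KS lattice statistics for many weight (label) vectors at once.

    order: (n, p) per-column argsort of the data matrix.
    valid: (n, p) True at the last position of each run of tied values.
    W:     (m, n) rows of group weights (+n2 for group 1, -n1 for group 2).
    Returns (m, p) integer statistics max|cumsum|.
    """
    order = np.ascontiguousarray(order, dtype=np.int64)
    valid = np.ascontiguousarray(valid)
    W = np.ascontiguousarray(W, dtype=np.int64)
    if _HAVE_NUMBA:
        return _ks_d_batch_nb(order, valid, W)
    return _ks_d_batch_numpy(order, valid, W)


def sort_structure(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column argsort and tie-run-end mask, computed once per matrix."""
    order = np.argsort(Z, axis=0, kind="stable")
    zs = np.take_along_axis(Z, order, axis=0)
    valid = np.ones_like(zs, dtype=bool)
    valid[:-1] = zs[:-1] != zs[1:]
    return order, valid


# ---------------------------------------------------------------------------
# shared helpers


def _perm_matrix(rng: np.random.Generator, B: int, n: int) -> np.ndarray:
    perms = np.empty((B, n), dtype=np.int64)
    for b in range(B):
        perms[b] = rng.permutation(n)
    return perms


def _pvalue(perm_stats: np.ndarray, observed: float, add_one: bool) -> float:
    count = int((perm_stats >= observed).sum())
    B = perm_stats.shape[0]
    if B == 0:  # statistic-only evaluation
        return 1.0
    if add_one:
        return (1 + count) / (1 + B)
    return count / B


# ---------------------------------------------------------------------------
# adaptive (AMDA) engine


def run_adaptive(
    Z: np.ndarray,
    y: np.ndarray,
    B: int,
    perm_rng: np.random.Generator,
    decoy_rng: np.random.Generator,
    rho: float | str = "median",
    ks_mode: str = "auto",
    reselect: bool = True,
    add_one: bool = False,
):
    """Adaptive permutation test on a CLR matrix.

    Returns (statistic, p_value, perm_stats, selection_info) where
    selection_info carries the observed selection mask, its real/decoy KS
    p-values and the decoy permutation.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    y = np.asarray(y, dtype=np.int64)
    n1 = int((y == 1).sum())
    n2 = n - n1
    if ks_mode == "auto":
        ks_mode = default_mode(n1, n2)

    order, valid = sort_structure(Z)
    w_base = np.where(y == 1, n2, -n1).astype(np.int64)

    # label permutations (row 0 = observed labels) and decoy permutations
    sigma = np.vstack([np.arange(n, dtype=np.int64), _perm_matrix(perm_rng, B, n)])
    pi_obs = decoy_rng.permutation(n)
    pis = np.vstack([pi_obs, _perm_matrix(decoy_rng, B, n)])

    W_real = w_base[sigma]                         # (B+1, n)
    inv = np.argsort(pis, axis=1)
    W_decoy = np.take_along_axis(W_real, inv, axis=1)

    D = ks_d_batch(order, valid, np.vstack([W_real, W_decoy]))
    D_real, D_decoy = D[: B + 1], D[B + 1:]
    masks = D_real > D_decoy                       # strict: p_j < p~_j
    if not reselect:
        masks = np.broadcast_to(masks[0], masks.shape).copy()

    iu0, iu1 = np.triu_indices(n, k=1)
    Ctri = (Z[iu0] - Z[iu1]) ** 2                  # (npairs, p)
    Dtri = Ctri @ masks.T.astype(float)            # (npairs, B+1)

    sizes = masks.sum(axis=1)
    nonempty = sizes > 0
    if isinstance(rho, str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rhos = np.median(Dtri, axis=0)
        if (nonempty & (rhos <= 0)).any():
            raise ValueError("median pairwise distance is zero on a selected subset")
        rhos = np.where(nonempty, rhos, 1.0)
    else:
        if rho <= 0:
            raise ValueError("rho must be positive")
        rhos = np.full(B + 1, float(rho))

    Ktri = np.exp(-Dtri / rhos[None, :])           # (npairs, B+1)

    vbase = np.where(y == 1, 1.0 / n1, -1.0 / n2)
    V = vbase[sigma]                               # (B+1, n)
    Vpair = V[:, iu0] * V[:, iu1]                  # (B+1, npairs)
    const = 1.0 / n1 + 1.0 / n2
    stats = const + 2.0 * np.einsum("bq,qb->b", Vpair, Ktri)
    stats[~nonempty] = 0.0

    observed = float(stats[0])
    perm_stats = stats[1:]
    pv = _pvalue(perm_stats, observed, add_one)

    selection = {
        "mask": masks[0],
        "pvals_real": ks_pvalues_from_d_int(D_real[0], n1, n2, mode=ks_mode),
        "pvals_decoy": ks_pvalues_from_d_int(D_decoy[0], n1, n2, mode=ks_mode),
        "decoy_permutation": pi_obs,
        "rho_observed": float(rhos[0]) if nonempty[0] else None,
        "ks_mode": ks_mode,
    }
    return observed, pv, perm_stats, selection


# ---------------------------------------------------------------------------
# plain MMD engine (no selection; kernel fixed across permutations)


def run_mmd(
    Z: np.ndarray,
    y: np.ndarray,
    B: int,
    perm_rng: np.random.Generator,
    rho: float | str = "median",
    add_one: bool = False,
):
    from .kernels import gram, KernelSpec

    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    y = np.asarray(y, dtype=np.int64)
    n1 = int((y == 1).sum())
    n2 = n - n1
    spec = KernelSpec("gaussian", rho).resolve(Z)
    K = gram(Z, spec)

    sigma = np.vstack([np.arange(n, dtype=np.int64), _perm_matrix(perm_rng, B, n)])
    vbase = np.where(y == 1, 1.0 / n1, -1.0 / n2)
    V = vbase[sigma]
    stats = np.einsum("bi,ij,bj->b", V, K, V, optimize=True)

    observed = float(stats[0])
    pv = _pvalue(stats[1:], observed, add_one)
    return observed, pv, stats[1:], {"rho": float(spec.rho)}


# ---------------------------------------------------------------------------
# MAX-type engine


def run_max(
    Z: np.ndarray,
    y: np.ndarray,
    B: int,
    perm_rng: np.random.Generator,
    variant: str = "standardized",
    add_one: bool = False,
):
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    y = np.asarray(y, dtype=np.int64)
    n1 = int((y == 1).sum())
    n2 = n - n1

    sigma = np.vstack([np.arange(n, dtype=np.int64), _perm_matrix(perm_rng, B, n)])
    G1 = (y[sigma] == 1).astype(float)             # (B+1, n)
    M1 = (G1 @ Z) / n1
    M2 = ((1.0 - G1) @ Z) / n2
    diff = M1 - M2

    if variant == "raw":
        stats_cols = np.abs(diff)
    elif variant == "standardized":
        Z2 = Z * Z
        S1 = G1 @ Z2
        S2 = (1.0 - G1) @ Z2
        var1 = (S1 - n1 * M1 * M1) / (n1 - 1)
        var2 = (S2 - n2 * M2 * M2) / (n2 - 1)
        denom = var1 / n1 + var2 / n2
        num = diff * diff
        with np.errstate(divide="ignore", invalid="ignore"):
            stats_cols = num / denom
        degenerate = denom <= 0
        if degenerate.any():
            # both groups constant: equal means contribute 0; unequal means
            # are an unbounded standardized difference, capped finite.
            blown = degenerate & (num > 0)
            if blown.any():
                warnings.warn(
                    "zero-variance column with unequal group means; "
                    "capping its MAX contribution", RuntimeWarning)
            stats_cols = np.where(degenerate, np.where(num > 0, MAX_STAT_CAP, 0.0),
                                  stats_cols)
    else:
        raise ValueError(f"unknown MAX variant {variant!r}")

    argmax = np.argmax(stats_cols, axis=1)
    stats = stats_cols[np.arange(B + 1), argmax]
    observed = float(stats[0])
    pv = _pvalue(stats[1:], observed, add_one)
    return observed, pv, stats[1:], {"argmax_column": int(argmax[0]), "variant": variant}
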