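"""Non-adaptive baseline tests sharing the AMDA p-value scheme.

``mmd_test`` is the plain kernel MMD permutation test on all p taxa, i.e.
the original two-sample MMD applied to the relative-abundance vectors
themselves (no subset selection, no log-ratio transform; the Gram matrix
and median-heuristic bandwidth are fixed across permutations since the
pooled rows never change).  A ``transform="clr"`` option kernels the CLR
matrix instead — on compositional data that variant behaves very
differently, because Euclidean distances between raw compositions are
dominated by the few most abundant taxa.

``max_test`` is the maximum-type test: the largest standardized squared
CLR mean difference across taxa, calibrated by the same label
permutations.  MAX looks only at the strongest single taxon, so it shines
when the signal is extremely sparse, while MMD aggregates everything and
suffers when most taxa are noise — AMDA sits between the two.
"""

from __future__ import annotations

import numpy as np

from ._engine import run_max, run_mmd
from .adaptive import TestResult, _prepare_clr, spawn_streams
from .kernels import KernelSpec
from .mmd import as_group_labels
from .transforms import AbundanceTable, replace_zeros, to_composition

__all__ = ["mmd_test", "max_test"]


def _prepare_composition(table, pseudo: float):
    if not isinstance(table, AbundanceTable):
        table = AbundanceTable(np.asarray(table, dtype=float))
    comp = to_composition(replace_zeros(table, pseudo))
    return comp.values, comp.taxa_ids


def mmd_test(
    table,
    y,
    B: int = 1000,
    spec: KernelSpec | None = None,
    seed: int | np.random.SeedSequence | None = 0,
    pseudo: float = 0.5,
    transform: str = "composition",
    add_one: bool = False,
    keep_permutation_stats: bool = False,
) -> TestResult:
    """Gaussian-kernel MMD^2 permutation test on the full taxa-set.

    By default the kernel is evaluated on the relative-abundance vectors
    (``transform="composition"``); ``transform="clr"`` kernels the
    centered log-ratio matrix instead.
    """
    labels = as_group_labels(y)
    labels.require_min_group_size(2)
    if B < 1:
        raise ValueError("B must be at least 1")
    if spec is None:
        spec = KernelSpec()
    if transform == "composition":
        Z, taxa = _prepare_composition(table, pseudo)
    elif transform == "clr":
        Z, taxa = _prepare_clr(table, pseudo)
    else:
        raise ValueError("transform must be 'composition' or 'clr'")
    if Z.shape[0] != labels.n:
        raise ValueError("label vector length does not match sample count")
    perm_rng, _ = spawn_streams(seed)
    stat, pv, perm_stats, info = run_mmd(
        Z, labels.labels, B, perm_rng, rho=spec.rho, add_one=add_one)
    return TestResult(
        statistic=stat,
        p_value=pv,
        selected_taxa=tuple(taxa),
        n_permutations=B,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
        method="mmd",
        permutation_stats=perm_stats if keep_permutation_stats else None,
        details={"rho": info["rho"], "transform": transform},
    )


def max_statistic(Z, y, variant: str = "standardized") -> float:
    """MAX statistic on a CLR matrix: the largest per-taxon group contrast.

    standardized: max_j (mean1_j - mean2_j)^2 / (s1_j^2/n1 + s2_j^2/n2);
    raw: max_j |mean1_j - mean2_j|.
    """
    labels = as_group_labels(y)
    rng = np.random.default_rng(0)  # unused: B=0 path below never permutes
    Z = np.asarray(Z, dtype=float)
    stat, _, _, _ = run_max(Z, labels.labels, 0, rng, variant=variant)
    return stat


def max_test(
    table,
    y,
    B: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
    pseudo: float = 0.5,
    variant: str = "standardized",
    add_one: bool = False,
    keep_permutation_stats: bool = False,
) -> TestResult:
    """Maximum-type permutation test on CLR-transformed abundances."""
    labels = as_group_labels(y)
    labels.require_min_group_size(2)
    if B < 1:
        raise ValueError("B must be at least 1")
    Z, taxa = _prepare_clr(table, pseudo)
    if Z.shape[0] != labels.n:
        raise ValueError("label vector length does not match sample count")
    perm_rng, _ = spawn_streams(seed)
    stat, pv, perm_stats, info = run_max(
        Z, labels.labels, B, perm_rng, variant=variant, add_one=add_one)
    return TestResult(
        statistic=stat,
        p_value=pv,
        selected_taxa=(taxa[info["argmax_column"]],),
        n_permutations=B,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
        method="max",
        permutation_stats=perm_stats if keep_permutation_stats else None,
        details={"argmax_taxon": taxa[info["argmax_column"]], "variant": variant},
    )
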