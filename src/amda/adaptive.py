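"""The adaptive two-sample test (AMDA) end to end.

``amda_test`` runs the full pipeline on an abundance table:

1. pseudo-count replacement, relative-abundance normalization and the
   centered log-ratio transform;
2. decoy-based selection of the testing subset S, then the Gaussian-kernel
   MMD^2 statistic on the S-columns, with the kernel bandwidth recomputed
   on those columns by the median heuristic;
3. B outer label permutations, *each of which repeats the selection* before
   recomputing the statistic — this re-selection is what keeps the
   permutation null exchangeable and the type I error at its nominal level;
4. the permutation p-value pv = (1/B) * #{b : MMD^2_b >= MMD^2_obs}.

An empty selection carries no evidence of a difference: its statistic is
defined as 0, so an empty selection on the observed data yields p-value 1.

Randomness: a master seed spawns independent child streams for the outer
label permutations, the decoy draws and (elsewhere) simulated data, so each
component can be replayed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._engine import run_adaptive
from .kernels import KernelSpec
from .mmd import GroupLabels, as_group_labels
from .subset_select import SubsetSelection
from .transforms import AbundanceTable, clr, replace_zeros, to_composition

__all__ = ["TestResult", "amda_test", "permute_labels", "spawn_streams"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a permutation two-sample test."""

    statistic: float
    p_value: float
    selected_taxa: tuple[str, ...]
    n_permutations: int
    seed: int | None
    method: str
    permutation_stats: np.ndarray | None = field(repr=False, default=None)
    selection: SubsetSelection | None = field(repr=False, default=None)
    details: dict[str, Any] = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        """JSON-serializable summary (deterministic key order)."""
        out: dict[str, Any] = {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n_permutations": int(self.n_permutations),
            "seed": self.seed,
            "selected_taxa": list(self.selected_taxa),
        }
        if self.selection is not None:
            sel = self.selection
            out["selection"] = {
                "taxa": list(self.selected_taxa),
                "pvals_real": [float(v) for v in sel.pvals_real],
                "pvals_decoy": [float(v) for v in sel.pvals_decoy],
            }
        out.update({k: v for k, v in self.details.items()
                    if isinstance(v, (int, float, str, bool, type(None)))})
        return out


def spawn_streams(seed) -> tuple[np.random.Generator, np.random.Generator]:
    """Master seed -> (outer-permutation stream, decoy stream)."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    perm_ss, decoy_ss, _ = ss.spawn(3)
    return np.random.default_rng(perm_ss), np.random.default_rng(decoy_ss)


def permute_labels(y, rng) -> GroupLabels:
    """Uniformly random permutation of the label vector (group sizes kept)."""
    labels = as_group_labels(y)
    if not hasattr(rng, "permutation"):
        rng = np.random.default_rng(rng)
    return GroupLabels(labels.labels[rng.permutation(labels.n)])


def _prepare_clr(table, pseudo: float) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(table, AbundanceTable):
        taxa = table.taxa_ids
    else:
        table = AbundanceTable(np.asarray(table, dtype=float))
        taxa = table.taxa_ids
    comp = to_composition(replace_zeros(table, pseudo))
    return clr(comp).values, taxa


def amda_test(
    table,
    y,
    B: int = 1000,
    spec: KernelSpec | None = None,
    seed: int | np.random.SeedSequence | None = 0,
    pseudo: float = 0.5,
    ks_mode: str = "auto",
    reselect_per_permutation: bool = True,
    add_one: bool = False,
    keep_permutation_stats: bool = False,
) -> TestResult:
    """Adaptive permutation test for a difference in taxa-set composition.

    Parameters
    ----------
    table : AbundanceTable or array
        Samples x taxa counts or relative abundances.
    y : GroupLabels or array of {1, 2}
        Group assignment; each group needs at least two samples.
    B : int
        Number of outer label permutations (>= 1).
    spec : KernelSpec
        Kernel family and bandwidth; default Gaussian with the median
        heuristic recomputed on each selected subset.
    seed : int or numpy SeedSequence
        Master seed; spawns independent permutation and decoy streams.
    ks_mode : {"auto", "exact", "asymp"}
        Marginal KS p-value mode used (identically) for real and decoy
        columns; "auto" is exact when n1*n2 <= 10^4.
    reselect_per_permutation : bool
        If False the observed subset is frozen across permutations.  This
        ablation inflates the type I error and exists only to demonstrate
        why re-selection is required; leave True for inference.
    add_one : bool
        Use the (1 + count)/(1 + B) p-value convention instead of count/B.
    """
    labels = as_group_labels(y)
    labels.require_min_group_size(2)
    if B < 1:
        raise ValueError("B must be at least 1")
    if spec is None:
        spec = KernelSpec()
    Z, taxa = _prepare_clr(table, pseudo)
    if Z.shape[0] != labels.n:
        raise ValueError("label vector length does not match sample count")

    perm_rng, decoy_rng = spawn_streams(seed)
    stat, pv, perm_stats, info = run_adaptive(
        Z, labels.labels, B, perm_rng, decoy_rng,
        rho=spec.rho, ks_mode=ks_mode,
        reselect=reselect_per_permutation, add_one=add_one,
    )
    mask = info["mask"]
    selection = SubsetSelection(
        selected=tuple(int(j) for j in np.flatnonzero(mask)),
        pvals_real=info["pvals_real"],
        pvals_decoy=info["pvals_decoy"],
        decoy_seed=seed if isinstance(seed, (int, np.integer)) else None,
        decoy_permutation=info["decoy_permutation"],
    )
    return TestResult(
        statistic=stat,
        p_value=pv,
        selected_taxa=tuple(taxa[j] for j in selection.selected),
        n_permutations=B,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
        method="amda",
        permutation_stats=perm_stats if keep_permutation_stats else None,
        selection=selection,
        details={"rho_observed": info["rho_observed"], "ks_mode": info["ks_mode"],
                 "subset_size": int(mask.sum())},
    )
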