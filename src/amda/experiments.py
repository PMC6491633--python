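"""Type-I-error and power experiments over a (p, n, sparsity) grid.

``run_cell`` estimates the rejection rate of one test in one simulation
scenario; ``run_experiment`` sweeps a grid and returns a tidy summary.
Rejection uses p-value <= alpha: the permutation p-value is a lattice
multiple of 1/B (including 0 and alpha itself), and the <= convention is
the one under which the nominal level is attainable.

Reproducibility contract: the seed of replicate r in cell c is derived
from (master_seed, c, r) alone, so summaries are identical for any worker
count or scheduling order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .adaptive import amda_test
from .comparators import max_test, mmd_test
from .simdata import SimulationScenario, generate_dataset

__all__ = ["ExperimentConfig", "ExperimentSummary", "run_cell", "run_experiment",
           "write_report"]

logger = logging.getLogger(__name__)

_TESTS: dict[str, Callable] = {
    "amda": lambda table, y, B, seed: amda_test(table, y, B=B, seed=seed),
    "mmd": lambda table, y, B, seed: mmd_test(table, y, B=B, seed=seed),
    "max": lambda table, y, B, seed: max_test(table, y, B=B, seed=seed),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid, tests and replicate budget for one experiment run."""

    grid: tuple[SimulationScenario, ...]
    tests: tuple[str, ...] = ("amda", "mmd", "max")
    alpha: float = 0.05
    n_replicates_null: int = 5000
    n_replicates_alt: int = 1000
    B: int = 1000
    master_seed: int = 0
    workers: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_replicates_null < 1 or self.n_replicates_alt < 1:
            raise ValueError("replicate counts must be >= 1")
        unknown = set(self.tests) - set(_TESTS)
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}")
        object.__setattr__(self, "grid", tuple(self.grid))
        object.__setattr__(self, "tests", tuple(self.tests))

    @classmethod
    def reduced(cls, **overrides) -> "ExperimentConfig":
        """Desk-scale profile: small grid, 500/300 replicates, B = 500."""
        grid = tuple(
            SimulationScenario(p=p, n=n, sparsity=0.3, null_model=True)
            for p in (50, 100) for n in (50, 100)
        )
        defaults = dict(grid=grid, n_replicates_null=500, n_replicates_alt=300,
                        B=500)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        grid = tuple(SimulationScenario(**cell) for cell in raw.pop("grid"))
        tests = tuple(raw.pop("tests", ("amda", "mmd", "max")))
        return cls(grid=grid, tests=tests, **raw)


@dataclass(frozen=True)
class ExperimentSummary:
    """Tidy rejection-rate table, one row per (scenario, test)."""

    frame: pd.DataFrame = field(repr=False)

    def rate(self, test: str, **scenario_fields) -> float:
        df = self.frame[self.frame["test"] == test]
        for key, val in scenario_fields.items():
            df = df[df[key] == val]
        if len(df) != 1:
            raise KeyError(f"selection matched {len(df)} rows, expected 1")
        return float(df["rejection_rate"].iloc[0])


def _replicate_pvalue(scenario: SimulationScenario, test: str, B: int,
                      master_seed: int, cell_id: int, rep: int) -> float:
    ss = np.random.SeedSequence([int(master_seed), int(cell_id), int(rep)])
    data_ss, test_ss = ss.spawn(2)
    table, labels, _ = generate_dataset(scenario.with_seed(data_ss))
    result = _TESTS[test](table, labels, B, test_ss)
    return result.p_value


def run_cell(
    scenario: SimulationScenario,
    test: str,
    config: ExperimentConfig,
    cell_id: int = 0,
    n_replicates: int | None = None,
    return_pvalues: bool = False,
):
    """Monte-Carlo rejection rate of one test in one scenario.

    Returns a dict with rejection_rate, mc_stderr (binomial) and
    n_replicates; optionally the raw p-value vector.
    """
    if n_replicates is None:
        n_replicates = (config.n_replicates_null if scenario.null_model
                        else config.n_replicates_alt)
    runner = delayed(_replicate_pvalue)
    if config.workers > 1:
        pvals = Parallel(n_jobs=config.workers)(
            runner(scenario, test, config.B, config.master_seed, cell_id, rep)
            for rep in range(n_replicates))
    else:
        pvals = [_replicate_pvalue(scenario, test, config.B, config.master_seed,
                                   cell_id, rep) for rep in range(n_replicates)]
    pvals = np.asarray(pvals)
    rate = float((pvals <= config.alpha).mean())
    stderr = float(np.sqrt(rate * (1.0 - rate) / n_replicates))
    out = {"rejection_rate": rate, "mc_stderr": stderr,
           "n_replicates": int(n_replicates)}
    if return_pvalues:
        out["pvalues"] = pvals
    return out


def run_experiment(config: ExperimentConfig) -> ExperimentSummary:
    """Sweep every (scenario, test) cell of the grid."""
    rows = []
    cell_id = 0
    for scenario in config.grid:
        for test in config.tests:
            res = run_cell(scenario, test, config, cell_id=cell_id)
            rows.append({
                "p": scenario.p, "n": scenario.n,
                "sparsity": scenario.sparsity,
                "null_model": scenario.null_model,
                "test": test,
                "rejection_rate": res["rejection_rate"],
                "mc_stderr": res["mc_stderr"],
                "n_replicates": res["n_replicates"],
            })
            logger.info("cell p=%d n=%d sparsity=%.2f null=%s test=%s rate=%.4f",
                        scenario.p, scenario.n, scenario.sparsity,
                        scenario.null_model, test, res["rejection_rate"])
            cell_id += 1
    return ExperimentSummary(pd.DataFrame(rows))


def _pivot(df: pd.DataFrame, tests: Sequence[str]) -> pd.DataFrame:
    wide = df.pivot_table(index=["p", "n"], columns="test",
                          values="rejection_rate", sort=False)
    return wide.reindex(columns=[t for t in tests if t in wide.columns])


def _markdown_table(wide: pd.DataFrame) -> str:
    cols = list(wide.columns)
    header = "| p | n | " + " | ".join(cols) + " |"
    sep = "|" + "---|" * (2 + len(cols))
    body = []
    for (p, n), row in wide.iterrows():
        cells = " | ".join(f"{row[c]:.4f}" for c in cols)
        body.append(f"| {p} | {n} | {cells} |")
    return "\n".join([header, sep, *body])


def write_report(summary: ExperimentSummary, out_dir,
                 tests: Sequence[str] | None = None) -> dict[str, Path]:
    """Write the summary as TSV (long) plus Markdown pivot tables.

    Produces ``summary.tsv`` (one row per cell, with stderr and replicate
    counts) and ``report.md`` (a type-I-error table shaped rows p x n,
    columns tests, plus one power table per sparsity level).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {out_dir}: {exc}") from exc
    df = summary.frame
    tests = list(tests) if tests is not None else list(dict.fromkeys(df["test"]))

    tsv_path = out_dir / "summary.tsv"
    df.to_csv(tsv_path, sep="\t", index=False)

    lines: list[str] = []
    nulls = df[df["null_model"]]
    if len(nulls):
        lines.append("## Empirical type I error (alpha-level rejection rate)\n")
        lines.append(_markdown_table(_pivot(nulls, tests)))
        lines.append("")
    alts = df[~df["null_model"]]
    for sp in sorted(alts["sparsity"].unique()):
        lines.append(f"## Empirical power, sparsity {sp:.0%}\n")
        lines.append(_markdown_table(_pivot(alts[alts["sparsity"] == sp], tests)))
        lines.append("")
    md_path = out_dir / "report.md"
    md_path.write_text("\n".join(lines))
    return {"tsv": tsv_path, "markdown": md_path}
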