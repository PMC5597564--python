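"""Benchmark harness: repeated seeded runs, aggregate tables, box-plot
statistics, convergence traces and pairwise rank-sum tests.

The experimental design mirrors the standard docking-benchmark protocol:
each algorithm is run R times independently per problem instance (seeds
``base_seed + run_index``); per cell the harness reports the lowest final
energy, the smallest RMSD and the success count (runs with RMSD strictly
below 2.0 Å).  Algorithm pairs are compared with a one-sided
Wilcoxon-Mann-Whitney rank-sum test on their final energies — exact
enumeration for arms of up to ten runs, tie-correction-free normal
approximation beyond — whose mirrored one-sided p-value structure matches
how stochastic optimizers are conventionally compared at the 0.05 level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pose import is_valid_pose
from .search import Problem, RunSummary, SearchConfig, run_cepga, run_ga

__all__ = [
    "ALGORITHMS",
    "RunTrace",
    "ComparisonTable",
    "PairwiseResult",
    "run_experiment",
    "box_stats",
    "pairwise_test",
    "plot_convergence",
    "plot_box",
]

logger = logging.getLogger(__name__)

ALGORITHMS: dict[str, Callable[[Problem, SearchConfig, int], RunSummary]] = {
    "cepga": lambda p, c, s: run_cepga(p, c, s),
    "ga": lambda p, c, s: run_ga(p, c, s),
    "ga+ls": lambda p, c, s: run_ga(p, c, s, local_search_enabled=True),
}


@dataclass(frozen=True)
class RunTrace:
    """Best-energy-vs-evaluations series of one run, validated on ingest:
    the energy must be strictly decreasing and the evaluation counts
    strictly increasing (a violation indicates an accounting bug)."""

    series: tuple[tuple[int, float], ...]
    final_energy: float
    final_rmsd: float | None
    seed: int
    algorithm: str
    instance: str = ""

    def __post_init__(self) -> None:
        ns = [n for n, _ in self.series]
        es = [e for _, e in self.series]
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValueError("trace evaluation counts must be strictly increasing")
        if any(b >= a for a, b in zip(es, es[1:])):
            raise ValueError("trace best energy must be strictly decreasing")

    @classmethod
    def from_summary(cls, summary: RunSummary, instance: str = "") -> "RunTrace":
        return cls(
            series=tuple(summary.trace),
            final_energy=summary.best_energy,
            final_rmsd=summary.best_rmsd,
            seed=summary.seed,
            algorithm=summary.algorithm,
            instance=instance,
        )


@dataclass
class ComparisonTable:
    """Per (instance, algorithm) aggregates over R runs."""

    frame: pd.DataFrame  # instance, algorithm, runs, lowest_energy, smallest_rmsd,
    #                      success_count, failures
    energies: dict[tuple[str, str], list[float]] = field(default_factory=dict)

    def cell_energies(self, instance: str, algorithm: str) -> list[float]:
        return self.energies[(instance, algorithm)]


def run_experiment(
    instances: Sequence[tuple[str, Problem] | tuple[str, Callable[[], Problem]]],
    algorithms: Sequence[str],
    runs: int,
    config: SearchConfig,
    base_seed: int = 0,
) -> tuple[ComparisonTable, list[RunTrace]]:
    """R independent seeded runs per (instance, algorithm) cell.

    Seeds are ``base_seed + run_index`` and recorded in every trace for
    exact replay.  A crashing run is logged and recorded as a failure; the
    experiment continues.
    """
    if runs < 1:
        raise ValueError("need at least one run per cell")
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")
    rows = []
    traces: list[RunTrace] = []
    energies: dict[tuple[str, str], list[float]] = {}
    for inst_name, inst in instances:
        for algo in algorithms:
            cell_e: list[float] = []
            cell_r: list[float] = []
            n_success = 0
            n_fail = 0
            for r in range(runs):
                try:
                    problem = inst() if callable(inst) else inst
                    summary = ALGORITHMS[algo](problem, config, base_seed + r)
                except Exception:  # noqa: BLE001 - record and continue
                    logger.exception(
                        "run failed: %s/%s seed=%d", inst_name, algo, base_seed + r
                    )
                    n_fail += 1
                    continue
                traces.append(RunTrace.from_summary(summary, inst_name))
                cell_e.append(summary.best_energy)
                if summary.best_rmsd is not None:
                    cell_r.append(summary.best_rmsd)
                    if is_valid_pose(summary.best_rmsd):
                        n_success += 1
            energies[(inst_name, algo)] = cell_e
            rows.append(
                dict(
                    instance=inst_name,
                    algorithm=algo,
                    runs=runs,
                    lowest_energy=min(cell_e) if cell_e else math.nan,
                    smallest_rmsd=min(cell_r) if cell_r else math.nan,
                    success_count=n_success,
                    failures=n_fail,
                )
            )
    return ComparisonTable(pd.DataFrame(rows), energies), traces


def box_stats(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """Tukey box-plot statistics ``(lower edge, Q1, median, Q3, upper edge)``.

    Quartiles use linear interpolation; the edges are the most extreme data
    points within 1.5 IQR of the quartiles (whisker convention).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("box_stats needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    in_lo = v[v >= q1 - 1.5 * iqr]
    in_hi = v[v <= q3 + 1.5 * iqr]
    return float(in_lo.min()), float(q1), float(med), float(q3), float(in_hi.max())


@dataclass(frozen=True)
class PairwiseResult:
    """One-sided rank-sum outcome for 'sample a yields lower energies than
    sample b'."""

    p_value: float
    statistic: float
    method: str  # "exact" | "asymptotic" | "degenerate"
    all_tied: bool = False


def pairwise_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> PairwiseResult:
    """One-sided Wilcoxon-Mann-Whitney test of ``a < b`` on final energies.

    Exact permutation enumeration when both arms have at most ten values and
    no ties straddle the samples; otherwise the normal approximation without
    continuity correction, whose complementary one-sided p-values sum to
    exactly 1.  Completely tied samples short-circuit to p = 0.5 with the
    ``all_tied`` flag set.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return PairwiseResult(0.5, a.size * b.size / 2.0, "degenerate", True)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size <= 10 and b.size <= 10 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="less", method="exact")
        return PairwiseResult(float(res.pvalue), float(res.statistic), "exact")
    res = stats.mannwhitneyu(
        a, b, alternative="less", method="asymptotic", use_continuity=False
    )
    return PairwiseResult(float(res.pvalue), float(res.statistic), "asymptotic")


# ---------------------------------------------------------------------------
# plotting (matplotlib imported lazily; figures written to files)


def plot_convergence(traces: Sequence[RunTrace], path: str | Path) -> None:
    """Best-energy vs evaluation-count step curves, one per run, grouped by
    algorithm color."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = {}
    cycle = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for tr in traces:
        if tr.algorithm not in colors:
            colors[tr.algorithm] = cycle[len(colors) % len(cycle)]
        ns = [n for n, _ in tr.series]
        es = [e for _, e in tr.series]
        ax.step(
            ns + [max(ns)],
            es + [es[-1]],
            where="post",
            color=colors[tr.algorithm],
            alpha=0.6,
            label=tr.algorithm,
        )
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys())
    ax.set_xlabel("energy evaluations $N_{eval}$")
    ax.set_ylabel("best energy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_box(
    samples: dict[str, Sequence[float]], path: str | Path, ylabel: str = "final energy"
) -> None:
    """Box plots of per-run final energies, one box per algorithm."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    names = list(samples)
    ax.boxplot([np.asarray(samples[n], dtype=float) for n in names],
               tick_labels=names, whis=1.5)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
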