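"""Repeated-run benchmarking of the feature-selection algorithms.

Reproduces the usual metaheuristic-FS evaluation protocol: each algorithm
is run ``n_runs`` times (default 30) with paired seeds — run ``r`` of every
algorithm uses ``base_seed + r``, so all algorithms see the same train/test
split — and the per-run accuracy, subset size, fitness and runtime are
aggregated into mean/std summaries.  Pairwise differences are labelled
'+', '-' or '~' by a two-sided Wilcoxon rank-sum test at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .feature_selection import FitnessSpec, FSResult, select_features
from .mswoa import MSWOAConfig

__all__ = ["TrialSummary", "run_trials", "significance_label", "export_tables"]


@dataclass
class TrialSummary:
    """Aggregate of one algorithm's repeated runs on one dataset."""

    dataset: str
    algorithm: str
    n_runs: int
    mean_accuracy: float
    std_accuracy: float
    mean_selected: float
    mean_fitness: float
    std_fitness: float
    mean_runtime: float
    runs: list[FSResult] = field(default_factory=list)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.test_accuracy for r in self.runs])

    @property
    def fitnesses(self) -> np.ndarray:
        return np.array([r.fitness for r in self.runs])

    @property
    def selected_counts(self) -> np.ndarray:
        return np.array([r.n_selected for r in self.runs])

    def mean_history(self) -> np.ndarray:
        """Convergence curve averaged over runs (truncated to common length)."""
        n = min(len(r.history) for r in self.runs)
        return np.mean([r.history[:n] for r in self.runs], axis=0)


def run_trials(x: np.ndarray, y: np.ndarray, algorithms: list[str],
               config: MSWOAConfig | None = None,
               spec: FitnessSpec | None = None, n_runs: int = 30,
               base_seed: int = 42, dataset_name: str = "dataset") -> list[TrialSummary]:
    """Run every algorithm ``n_runs`` times with paired seeds and summarize.

    A failing run is recorded as a warning and excluded; ``n_runs`` in the
    summary reflects the successful count.
    """
    summaries = []
    for algo in algorithms:
        results: list[FSResult] = []
        for r in range(n_runs):
            try:
                results.append(select_features(x, y, algorithm=algo, config=config,
                                               spec=spec, seed=base_seed + r))
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"run {r} of {algo} failed: {exc}", stacklevel=2)
        acc = np.array([res.test_accuracy for res in results])
        fit = np.array([res.fitness for res in results])
        summaries.append(TrialSummary(
            dataset=dataset_name, algorithm=algo, n_runs=len(results),
            mean_accuracy=float(acc.mean()), std_accuracy=float(acc.std()),
            mean_selected=float(np.mean([res.n_selected for res in results])),
            mean_fitness=float(fit.mean()), std_fitness=float(fit.std()),
            mean_runtime=float(np.mean([res.wall_time for res in results])),
            runs=results))
    return summaries


def significance_label(sample_a, sample_b, alpha_level: float = 0.05,
                       higher_is_better: bool = True) -> str:
    """'+', '-' or '~' for algorithm A vs B on run-level metric samples.

    Two-sided Wilcoxon rank-sum; '+' when the difference is significant and
    A's mean is better, '-' when significant and worse, '~' otherwise.
    Identical samples (or samples too small to test, n < 3) are '~'.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if a.size < 3 or b.size < 3:
        warnings.warn("fewer than 3 runs per sample; reporting '~'", stacklevel=2)
        return "~"
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        return "~"
    _, p = ranksums(a, b)
    if p >= alpha_level:
        return "~"
    better = a.mean() > b.mean() if higher_is_better else a.mean() < b.mean()
    return "+" if better else "-"


def export_tables(summaries: list[TrialSummary], metric: str = "mean_accuracy",
                  higher_is_better: bool = True, out_csv=None, out_md=None) -> pd.DataFrame:
    """Dataset x algorithm table of a summary metric with Ave and Rank rows.

    The best value per dataset row is bolded in the Markdown rendering; the
    Ave row holds per-algorithm column means and the Rank row ranks the
    algorithms by that average (1 = best).
    """
    datasets = sorted({s.dataset for s in summaries})
    algorithms = sorted({s.algorithm for s in summaries})
    table = pd.DataFrame(index=datasets, columns=algorithms, dtype=float)
    for s in summaries:
        table.loc[s.dataset, s.algorithm] = getattr(s, metric)
    ave = table.mean(axis=0)
    rank = ave.rank(ascending=not higher_is_better, method="first").astype(int)
    full = pd.concat([table, pd.DataFrame([ave, rank.astype(float)],
                                          index=["Ave", "Rank"])])
    if out_csv is not None:
        full.to_csv(out_csv)
    if out_md is not None:
        lines = ["| Dataset | " + " | ".join(algorithms) + " |",
                 "|" + "---|" * (len(algorithms) + 1)]
        for ds in datasets:
            row = table.loc[ds]
            best = row.max() if higher_is_better else row.min()
            cells = [f"**{v:.4f}**" if v == best else f"{v:.4f}" for v in row]
            lines.append(f"| {ds} | " + " | ".join(cells) + " |")
        lines.append("| Ave | " + " | ".join(f"{v:.4f}" for v in ave) + " |")
        lines.append("| Rank | " + " | ".join(str(v) for v in rank) + " |")
        with open(out_md, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    return full
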