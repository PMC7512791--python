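"""Structure-recovery metrics and the benchmark experiment runner.

Recovery is measured on exact directed-edge identity over the union of
inter- and intra-slice edges of a transition network:

    precision = TP / (TP + FP),  recall = TP / (TP + FN),
    F1 = 2 * precision * recall / (precision + recall),

with the degenerate 0/0 cases reported as 0 so that means over trials stay
defined.  The experiment runner repeats generate -> sample -> learn ->
compare over several trials and sample sizes and annotates the mean metrics
with 95% confidence intervals.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .learn import LearnConfig, learn_tdbn, learn_transition, make_scorer
from .model import TransitionStructure
from .simulate import GeneratorConfig, build_model, random_cpts, random_structure, sample_dataset

__all__ = [
    "RecoveryMetrics",
    "transition_edges",
    "compare_structures",
    "run_experiment",
    "default_learners",
    "format_results",
]


@dataclass(frozen=True)
class RecoveryMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "RecoveryMetrics":
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        return cls(tp, fp, fn, precision, recall, f1)


def transition_edges(structure: TransitionStructure) -> frozenset:
    """Directed edges of a transition network as (slice, source, target)
    triples; intra edges carry slice == m."""
    edges = set()
    for i in range(structure.n):
        for sv in structure.past_parents[i]:
            edges.add((sv.slice, sv.attr, i))
        for j in structure.intra_parents[i]:
            edges.add((structure.m, j, i))
    return frozenset(edges)


def compare_structures(
    truth: TransitionStructure, learned: TransitionStructure
) -> RecoveryMetrics:
    """Exact directed-edge recovery of ``learned`` against ``truth``."""
    if truth.n != learned.n or truth.m != learned.m:
        raise ValueError("structures have mismatched shapes")
    te = transition_edges(truth)
    le = transition_edges(learned)
    tp = len(te & le)
    return RecoveryMetrics.from_counts(tp=tp, fp=len(le - te), fn=len(te - le))


def recovery_trials(
    gen_cfg: GeneratorConfig,
    N: int,
    cfg: LearnConfig,
    algorithm: str = "bcdbn",
    trials: int = 5,
    seed: int = 1,
) -> list[RecoveryMetrics]:
    """Repeat generate -> sample -> learn -> compare; trial t is seeded
    ``seed + t`` and drives structure, CPTs and sampling from one stream."""
    out = []
    for trial in range(trials):
        rng = np.random.default_rng(seed + trial)
        truth = random_structure(gen_cfg, rng)
        cpts = random_cpts(truth, gen_cfg, rng)
        model = build_model(truth, cpts, gen_cfg.r)
        data = sample_dataset(model, N, gen_cfg.m, rng=rng)
        if algorithm == "tdbn":
            learned = learn_tdbn(data, cfg)
        else:
            learned = learn_transition(data, cfg)
        out.append(compare_structures(truth, learned))
    return out


def default_learners(p: int, k: int, m: int = 1) -> dict[str, tuple[str, LearnConfig]]:
    """The four learner/criterion combinations used in the benchmarks."""
    from .scores import ScoreSpec

    out: dict[str, tuple[str, LearnConfig]] = {}
    for crit in ("ll", "mdl"):
        spec = ScoreSpec(crit)
        out[f"tDBN+{crit.upper()}"] = ("tdbn", LearnConfig(m=m, p=p, k=1, score=spec))
        out[f"bcDBN+{crit.upper()}"] = ("bcdbn", LearnConfig(m=m, p=p, k=k, score=spec))
    return out


def _halfwidth(values: np.ndarray, ci: str) -> float:
    t = len(values)
    if t < 2:
        return 0.0
    sd = float(np.std(values, ddof=1))
    if ci == "t":
        from scipy import stats

        crit = float(stats.t.ppf(0.975, t - 1))
    else:
        crit = 1.96
    return crit * sd / np.sqrt(t)


def run_experiment(
    gen_cfg: GeneratorConfig,
    learners: Mapping[str, tuple[str, LearnConfig]],
    N_grid: Sequence[int],
    trials: int = 5,
    seed: int = 1,
    T: Optional[int] = None,
    ci: str = "normal",
) -> pd.DataFrame:
    """Structure-recovery benchmark over a grid of sample sizes.

    Per trial ``t`` (seeded ``seed + t``): draw a truth network and CPTs,
    sample a dataset, run every learner, and score recovery against the
    truth.  ``T`` defaults to the Markov lag, so ``N`` counts transition
    rows.  Returns one row per (learner, N) with mean and 95%-CI half-width
    for precision, recall and F1 (``ci="normal"`` uses 1.96*sd/sqrt(trials);
    ``ci="t"`` the small-sample t quantile).
    """
    if trials < 2:
        raise ValueError("need at least 2 trials for a confidence interval")
    T = gen_cfg.m if T is None else T
    records = []
    for trial in range(trials):
        trial_seed = seed + trial
        rng = np.random.default_rng(trial_seed)
        truth = random_structure(gen_cfg, rng)
        cpts = random_cpts(truth, gen_cfg, rng)
        model = build_model(truth, cpts, gen_cfg.r)
        data_full = sample_dataset(model, max(N_grid), T, rng=rng)
        for N in N_grid:
            data = type(data_full)(
                values=data_full.values[:N], attrs=list(data_full.attrs)
            )
            for name, (algorithm, cfg) in learners.items():
                start = time.perf_counter()
                scorer = make_scorer(data, cfg)
                if algorithm == "tdbn":
                    learned = learn_tdbn(data, cfg, scorer=scorer)
                else:
                    learned = learn_transition(data, cfg, scorer=scorer)
                elapsed = time.perf_counter() - start
                metrics = compare_structures(truth, learned)
                records.append(
                    dict(
                        learner=name, N=N, trial=trial, seed=trial_seed,
                        precision=metrics.precision, recall=metrics.recall,
                        f1=metrics.f1, seconds=elapsed,
                    )
                )
    raw = pd.DataFrame.from_records(records)
    rows = []
    for (name, N), grp in raw.groupby(["learner", "N"], sort=False):
        row = dict(learner=name, N=N, trials=len(grp))
        for metric in ("precision", "recall", "f1"):
            vals = grp[metric].to_numpy()
            row[metric] = float(np.mean(vals))
            row[f"{metric}_ci"] = _halfwidth(vals, ci)
        row["seconds"] = float(grp["seconds"].mean())
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["learner", "N"]).reset_index(drop=True)


def format_results(df: pd.DataFrame) -> str:
    """Pretty-print a results table: percentages with CI half-widths."""
    lines = []
    header = f"{'learner':<12} {'N':>6}  {'Pre.':>12} {'Rec.':>12} {'F1':>12} {'Time(s)':>8}"
    lines.append(header)
    lines.append("-" * len(header))
    for _, row in df.iterrows():
        cells = []
        for metric in ("precision", "recall", "f1"):
            cells.append(
                f"{100 * row[metric]:5.1f}±{100 * row[f'{metric}_ci']:4.1f}"
            )
        lines.append(
            f"{row['learner']:<12} {int(row['N']):>6}  "
            f"{cells[0]:>12} {cells[1]:>12} {cells[2]:>12} {row['seconds']:>8.2f}"
        )
    return "\n".join(lines)
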