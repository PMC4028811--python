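"""The masking-simulation benchmark and algorithm selection.

Protocol: starting from a complete matrix, repeat for every missing rate
and every round — hide entries at random, let every competing algorithm
impute the *same* masked matrix, and score each result with NRMSE, CPP
and (given class labels) BLCI.  Per round and index the algorithms are
ranked (ties averaged), ranks are averaged over rounds with a standard
error, the three per-index average ranks are averaged into the "average
index", and the winner for a user's dataset is the algorithm with the
smallest mean NRMSE (or best average index) across the simulation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import registry
from .exceptions import ArrayImputeError, SelectionError, ValidationError
from .masking import apply_mask, derive_seed, inject_missing
from .matrix import ExpressionMatrix, filter_complete
from .metrics import ScoreRecord, score_round

logger = logging.getLogger(__name__)

DEFAULT_RATES = (0.01, 0.05, 0.10, 0.15, 0.20)

#: Whether a larger index value is better, per index.
ORIENTATION = {"nrmse": "lower_better", "cpp": "higher_better", "blci": "higher_better"}


@dataclass
class BenchmarkPlan:
    """Everything needed to reproduce one benchmark run."""

    dataset: ExpressionMatrix
    algorithms: Sequence[str | tuple[str, object]]
    rates: Sequence[float] = DEFAULT_RATES
    rounds: int = 110
    master_seed: int = 0
    indices: tuple[str, ...] = ("nrmse", "cpp", "blci")
    dataset_name: str = "dataset"
    n_clusters: int = 10

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise ValidationError("plan needs at least one algorithm")
        if not all(0.0 < r <= 0.5 for r in self.rates):
            raise ValidationError("rates must lie in (0, 0.5]")
        if self.rounds < 1:
            raise ValidationError("rounds must be >= 1")

    def algorithm_items(self) -> list[tuple[str, object]]:
        out = []
        for a in self.algorithms:
            if isinstance(a, str):
                name = registry.resolve(a)
                out.append((name, registry.default_config(name, self.dataset.dataset_type)))
            else:
                name, cfg = a
                out.append((registry.resolve(name), cfg))
        return out


def run_benchmark(plan: BenchmarkPlan) -> list[ScoreRecord]:
    """Execute the full rate x round x algorithm simulation."""
    complete = filter_complete(plan.dataset)
    algos = plan.algorithm_items()
    labels = complete.class_labels
    records: list[ScoreRecord] = []
    for rate in plan.rates:
        for rnd in range(plan.rounds):
            mask_seed = derive_seed(plan.master_seed, "mask", rnd, rate)
            masked = inject_missing(complete, rate, mask_seed)
            m_missing = apply_mask(masked)
            score_seed = derive_seed(plan.master_seed, "score", rnd, rate)
            for name, cfg in algos:
                try:
                    _, fn = registry.get_algorithm(name)
                    if name in registry.NEEDS_TRUTH:
                        result = fn(m_missing, cfg, masked=masked)
                    else:
                        result = fn(m_missing, cfg) if cfg is not None else fn(m_missing)
                    rec = score_round(masked, result, labels=labels, seed=score_seed,
                                      dataset=plan.dataset_name, round_no=rnd,
                                      n_clusters=plan.n_clusters, indices=plan.indices)
                except ArrayImputeError as exc:
                    logger.warning("%s failed on round %d rate %s: %s", name, rnd, rate, exc)
                    rec = ScoreRecord(algorithm=name, dataset=plan.dataset_name,
                                      rate=rate, round=rnd, meta={"error": str(exc)})
                records.append(rec)
    return records


def records_to_frame(records: Iterable[ScoreRecord]) -> pd.DataFrame:
    rows = [{"dataset": r.dataset, "algorithm": r.algorithm, "rate": r.rate,
             "round": r.round, "nrmse": r.nrmse, "cpp": r.cpp, "blci": r.blci}
            for r in records]
    return pd.DataFrame(rows)


def write_scores(records: Iterable[ScoreRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def write_manifest(plan: BenchmarkPlan, path) -> None:
    d = {"dataset_name": plan.dataset_name,
         "shape": list(plan.dataset.shape),
         "dataset_type": plan.dataset.dataset_type,
         "algorithms": [n for n, _ in plan.algorithm_items()],
         "rates": list(plan.rates), "rounds": plan.rounds,
         "master_seed": plan.master_seed, "indices": list(plan.indices),
         "n_clusters": plan.n_clusters}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2)


def rank_per_round(scores: Mapping[str, float | None], orientation: str) -> dict[str, float]:
    """Rank one round's scores (1 = best); ties get the average position.

    Algorithms with a missing (None/NaN) score are excluded from the
    round; fewer than two defined scores means the round is skipped.
    """
    if orientation not in ("lower_better", "higher_better"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    defined = {a: v for a, v in scores.items() if v is not None and np.isfinite(v)}
    if len(defined) < 2:
        return {}
    names = list(defined)
    vals = np.array([defined[a] for a in names], dtype=float)
    if orientation == "higher_better":
        vals = -vals
    ranks = rankdata(vals, method="average")
    return {a: float(r) for a, r in zip(names, ranks)}


def average_rank(ranks: Sequence[float]) -> tuple[float, float]:
    """Mean rank over rounds and its standard error (sample SD / sqrt(n))."""
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise ValidationError("average_rank needs at least one round")
    if ranks.size == 1:
        return float(ranks[0]), 0.0
    return float(ranks.mean()), float(ranks.std(ddof=1) / np.sqrt(ranks.size))


@dataclass
class RankSummary:
    """Per-(algorithm, index) average ranks with standard errors.

    ``table`` is indexed by algorithm with a (avg_rank, std_error,
    n_rounds) column triple per index; ``average_index`` is the unweighted
    mean of the available per-index average ranks.
    """

    table: pd.DataFrame
    average_index: dict[str, float]
    indices: tuple[str, ...]

    @property
    def algorithms(self) -> list[str]:
        return list(self.table.index)

    def avg_rank(self, algorithm: str, index: str) -> float:
        return float(self.table.loc[algorithm, (index, "avg_rank")])


def summarize_ranks(records: Iterable[ScoreRecord],
                    indices: tuple[str, ...] = ("nrmse", "cpp", "blci")) -> RankSummary:
    """Per-round ranking followed by rank averaging, for every index."""
    df = records_to_frame(records)
    algorithms = list(dict.fromkeys(df["algorithm"]))
    per_algo_ranks: dict[str, dict[str, list[float]]] = {
        a: {ix: [] for ix in indices} for a in algorithms}
    for (_, _), grp in df.groupby(["rate", "round"], sort=True):
        for ix in indices:
            scores = {row.algorithm: getattr(row, ix) for row in grp.itertuples()}
            scores = {a: (None if v is None or (isinstance(v, float) and np.isnan(v)) else v)
                      for a, v in scores.items()}
            ranks = rank_per_round(scores, ORIENTATION[ix])
            for a, r in ranks.items():
                per_algo_ranks[a][ix].append(r)

    cols = {}
    for ix in indices:
        avg, se, n = [], [], []
        for a in algorithms:
            rk = per_algo_ranks[a][ix]
            if rk:
                mean, stderr = average_rank(rk)
            else:
                mean, stderr = np.nan, np.nan
            avg.append(mean)
            se.append(stderr)
            n.append(len(rk))
        cols[(ix, "avg_rank")] = avg
        cols[(ix, "std_error")] = se
        cols[(ix, "n_rounds")] = n
    table = pd.DataFrame(cols, index=pd.Index(algorithms, name="algorithm"))

    avg_index: dict[str, float] = {}
    for a in algorithms:
        vals = [table.loc[a, (ix, "avg_rank")] for ix in indices
                if np.isfinite(table.loc[a, (ix, "avg_rank")])]
        avg_index[a] = float(np.mean(vals)) if vals else float("nan")
    return RankSummary(table=table, average_index=avg_index, indices=tuple(indices))


def average_index(summary: RankSummary) -> dict[str, float]:
    """Unweighted mean of the available per-index average ranks."""
    return dict(summary.average_index)


@dataclass
class RobustnessReport:
    """Per-algorithm rank-shift between two dataset types."""

    sigma: dict[str, float]
    robust: dict[str, bool]
    threshold: float = 1.5


def robustness_sigma(summary_a: RankSummary, summary_b: RankSummary,
                     index: str = "average", threshold: float = 1.5) -> RobustnessReport:
    """sigma = |avg_rank_A - avg_rank_B| per algorithm; robust iff sigma < threshold."""
    if set(summary_a.algorithms) != set(summary_b.algorithms):
        raise ValidationError("summaries cover different algorithm sets")
    sig, rob = {}, {}
    for a in summary_a.algorithms:
        if index == "average":
            va, vb = summary_a.average_index[a], summary_b.average_index[a]
        else:
            va, vb = summary_a.avg_rank(a, index), summary_b.avg_rank(a, index)
        s = abs(va - vb)
        sig[a] = s
        rob[a] = bool(s < threshold)  # strict inequality
    return RobustnessReport(sigma=sig, robust=rob, threshold=threshold)


def rate_nrmse_table(records: Iterable[ScoreRecord]) -> pd.DataFrame:
    """Mean NRMSE per (rate, algorithm): the missing-rate-vs-error report."""
    df = records_to_frame(records)
    return df.pivot_table(index="rate", columns="algorithm", values="nrmse",
                          aggfunc="mean")


def select_optimal(records: Iterable[ScoreRecord], criterion: str = "mean_nrmse",
                   plan_order: Sequence[str] | None = None
                   ) -> tuple[str, pd.DataFrame]:
    """Pick the winning algorithm from the simulation records.

    ``mean_nrmse`` (default): smallest mean NRMSE over all rates and
    rounds.  ``average_index``: smallest average-index value.  Ties break
    by smaller mean NRMSE, then by plan order.  Also returns the
    rate-vs-mean-NRMSE table for reporting.
    """
    records = list(records)
    df = records_to_frame(records)
    mean_nrmse = df.groupby("algorithm")["nrmse"].mean()
    scorable = mean_nrmse.dropna()
    if scorable.empty:
        raise SelectionError("no algorithm produced a defined NRMSE")
    order = list(plan_order) if plan_order else list(dict.fromkeys(df["algorithm"]))

    if criterion == "mean_nrmse":
        primary = {a: float(scorable[a]) for a in scorable.index}
    elif criterion == "average_index":
        summary = summarize_ranks(records)
        primary = {a: v for a, v in summary.average_index.items()
                   if np.isfinite(v) and a in scorable.index}
        if not primary:
            raise SelectionError("average index undefined for every algorithm")
    else:
        raise ValidationError(f"unknown criterion {criterion!r}")

    def sort_key(a: str):
        return (primary[a], float(scorable.get(a, np.inf)),
                order.index(a) if a in order else len(order))

    winner = min(primary, key=sort_key)
    return winner, rate_nrmse_table(records)
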