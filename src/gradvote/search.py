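"""Exhaustive search over base-model subsets.

Every subset of size >= 2 of the tuned base models gets its own weight
fit; with five families that is C(5,2)+C(5,3)+C(5,4)+C(5,5) = 26
candidate ensembles. The best candidate is picked by accuracy on a
selection split — validation by default (leakage-free), with a test-set
mode available to mirror protocols that select on test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .base_models import FittedBaseModel, predict_matrix
from .datatable import DataSplit
from .metrics import MetricsReport, compute_report
from .optimizer import (
    OptimizationTrace,
    WeightOptimizerConfig,
    ensemble_predict,
    optimize_weights,
)

__all__ = ["EnsembleResult", "enumerate_combinations", "search", "results_to_frame"]


@dataclass
class EnsembleResult:
    """One fitted subset: its weights, metrics on each split, and trace."""

    subset: tuple[str, ...]
    weights: np.ndarray
    train_accuracy: float
    val_metrics: MetricsReport
    test_metrics: MetricsReport
    trace: OptimizationTrace
    init_seed: int


def enumerate_combinations(families, min_size: int = 2) -> list[tuple[str, ...]]:
    """All subsets of size min_size..n in lexicographic-by-index order."""
    families = list(families)
    n = len(families)
    if n < min_size:
        raise ValueError(f"need at least {min_size} families, got {n}")
    subsets: list[tuple[str, ...]] = []
    for k in range(min_size, n + 1):
        subsets.extend(combinations(families, k))
    return subsets


def _subset_seed(base_seed: int, index: int) -> int:
    # Independent per-subset stream, kept below 2**31 for portability.
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def search(
    models: list[FittedBaseModel],
    split: DataSplit,
    config: WeightOptimizerConfig | None = None,
    selection: str = "validation",
    min_size: int = 2,
) -> tuple[EnsembleResult, list[EnsembleResult]]:
    """Fit weights for every subset and pick the best.

    Ties on selection-split accuracy break by higher AUC on that split,
    then by smaller subset, then by enumeration order. Each subset's
    random weight initialization uses a seed derived from the config seed
    and the subset index, so results are reproducible subset by subset.
    """
    config = config or WeightOptimizerConfig()
    if selection not in ("validation", "test"):
        raise ValueError(f"selection must be 'validation' or 'test', got {selection!r}")
    families = [m.family for m in models]
    by_family = dict(zip(families, models))

    P = {name: predict_matrix(models, part) for name, part in split.parts().items()}
    row = {fam: i for i, fam in enumerate(families)}

    results: list[EnsembleResult] = []
    for idx, subset in enumerate(enumerate_combinations(families, min_size)):
        rows = [row[f] for f in subset]
        seed = _subset_seed(config.seed, idx)
        cfg = replace(config, seed=seed)
        w, trace = optimize_weights(
            P["train"][rows], split.train.y, P["val"][rows], split.val.y, cfg
        )
        yh_train = ensemble_predict(P["train"][rows], w)
        train_acc = float(np.mean((yh_train >= 0.5).astype(int) == split.train.y))
        val_report = compute_report(split.val.y, ensemble_predict(P["val"][rows], w))
        test_report = compute_report(split.test.y, ensemble_predict(P["test"][rows], w))
        results.append(
            EnsembleResult(
                subset=subset,
                weights=w,
                train_accuracy=train_acc,
                val_metrics=val_report,
                test_metrics=test_report,
                trace=trace,
                init_seed=seed,
            )
        )

    def sort_key(r: EnsembleResult):
        m = r.val_metrics if selection == "validation" else r.test_metrics
        return (-m.accuracy, -m.auc, len(r.subset))

    best = min(results, key=sort_key)  # stable: enumeration order breaks remaining ties
    return best, results


def results_to_frame(results: list[EnsembleResult]) -> pd.DataFrame:
    """Flatten search results into one row per subset for CSV export."""
    records = []
    for r in results:
        records.append(
            {
                "subset": "+".join(r.subset),
                "weights": "|".join(f"{w:.10g}" for w in r.weights),
                "train_accuracy": r.train_accuracy,
                "val_accuracy": r.val_metrics.accuracy,
                "val_auc": r.val_metrics.auc,
                "val_f1": r.val_metrics.f1,
                "test_accuracy": r.test_metrics.accuracy,
                "test_auc": r.test_metrics.auc,
                "test_f1": r.test_metrics.f1,
                "best_val_loss": r.trace.best_loss,
                "iterations_run": r.trace.iterations_run,
                "stop_reason": r.trace.stop_reason,
                "init_seed": r.init_seed,
            }
        )
    return pd.DataFrame.from_records(records)
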