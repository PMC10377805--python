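"""Experiment grid runner: feature-selection methods x feature counts x
classifiers, with bootstrap train/test metrics for each cell."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd

from nosomap.classify import (
    MetricsSummary,
    bootstrap_evaluate,
    select_best_model,
)
from nosomap.features import (
    BORUTA_DROP_THRESHOLDS,
    FeatureSet,
    rank_features,
    sffs_select,
    validate_k,
)

DEFAULT_CLASSIFIERS = ("lda", "svm", "rf")
DEFAULT_METHODS = ("sffs", "chi", "kbest", "lasso", "boruta")


@dataclass(frozen=True)
class GridCell:
    method: str
    k: "int | None"  # feature count; None for boruta drop-threshold cells
    drop_threshold: float
    classifier: str

    def label(self) -> str:
        if self.k is not None:
            return f"{self.method}/{self.k}/{self.classifier}"
        return (
            f"{self.method}/drop{int(self.drop_threshold * 100)}/"
            f"{self.classifier}"
        )


def grid_run(
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_test: np.ndarray,
    y_test: Sequence[str],
    methods: Sequence[str] = DEFAULT_METHODS,
    feature_counts: Sequence[int] = tuple(range(3, 11)),
    classifiers: Sequence[str] = DEFAULT_CLASSIFIERS,
    n_reps: int = 1000,
    seed: int = 0,
    boruta_params: dict | None = None,
) -> tuple[pd.DataFrame, GridCell, dict[GridCell, MetricsSummary]]:
    """Run the full experiment grid.

    Boruta cells sweep correlation-drop thresholds (50..90%) instead of
    feature counts, mirroring the reported experiment structure.  Returns
    a tidy table, the best cell by the AUC-ratio criterion, and the raw
    summaries.
    """
    for k in feature_counts:
        validate_k(k)
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    results: dict[GridCell, MetricsSummary] = {}
    feature_sets: dict[tuple, FeatureSet] = {}
    rows = []

    def run_cell(cell: GridCell, fset: FeatureSet) -> None:
        idx = list(fset.indices)
        if not idx:
            return
        ms = bootstrap_evaluate(
            X_train[:, idx],
            y_train,
            X_test[:, idx],
            y_test,
            method=cell.classifier,
            n_reps=n_reps,
            seed=seed,
        )
        results[cell] = ms
        rows.append(
            {
                "method": cell.method,
                "k": cell.k,
                "drop_threshold": cell.drop_threshold,
                "classifier": cell.classifier,
                "n_features": len(idx),
                "ber_train_mean": float(ms.ber_train.mean()),
                "ber_test_mean": float(ms.ber_test.mean()),
                "auc_train_mean": float(ms.auc_train.mean()),
                "auc_test_mean": float(ms.auc_test.mean()),
                "auc_ratio": ms.auc_ratio,
            }
        )

    for method in methods:
        if method == "boruta":
            for thr in BORUTA_DROP_THRESHOLDS:
                key = (method, None, thr)
                if key not in feature_sets:
                    feature_sets[key] = rank_features(
                        X_train,
                        y_train,
                        "boruta",
                        k=None,
                        drop_threshold=thr,
                        params=dict(boruta_params or {}, seed=seed),
                    )
                for clf in classifiers:
                    run_cell(
                        GridCell(method, None, thr, clf), feature_sets[key]
                    )
        else:
            for k in feature_counts:
                key = (method, k, 0.80)
                if key not in feature_sets:
                    if method == "sffs":
                        feature_sets[key] = sffs_select(
                            X_train, y_train, k, seed=seed
                        )
                    else:
                        feature_sets[key] = rank_features(
                            X_train,
                            y_train,
                            method,
                            k=k,
                            params={"seed": seed},
                        )
                for clf in classifiers:
                    run_cell(
                        GridCell(method, k, 0.80, clf), feature_sets[key]
                    )

    table = pd.DataFrame(rows)
    best = select_best_model(list(results.items()))
    return table, best, results


def pivot_ber(table: pd.DataFrame, split: str = "test") -> pd.DataFrame:
    """Methods x feature-count BER matrix (one block per classifier)."""
    col = f"ber_{split}_mean"
    return table.pivot_table(
        index=["classifier", "method"],
        columns="k",
        values=col,
        aggfunc="first",
    )
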