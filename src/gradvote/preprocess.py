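"""Preprocessing for clinical-style feature tables.

Covers the transformations needed before model fitting: binarizing a
multi-class target, replacing physiologically invalid zeros by a column
statistic, one-hot encoding and missing-value imputation fitted on the
training part only, min-max normalization, and stratified three-way
splitting. All fit/transform operations take an explicit ``fit_on`` table
so no statistic ever leaks from validation or test rows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .datatable import DataSplit, FeatureTable

__all__ = [
    "binarize_target",
    "impute_invalid_zeros",
    "encode_and_impute",
    "normalize",
    "stratified_split",
]


def binarize_target(table: FeatureTable, positive_classes) -> FeatureTable:
    """Map a multi-class label vector to {0, 1}.

    Every observed label in ``positive_classes`` becomes 1, all others 0.
    An empty set is allowed (all-negative) as is the full label set
    (all-positive); labels absent from both raise nothing — the mapping is
    total by construction.
    """
    positives = set(positive_classes)
    y = np.asarray([1 if label in positives else 0 for label in table.y], dtype=int)
    return FeatureTable(table.X.copy(), y)


def impute_invalid_zeros(
    table: FeatureTable,
    columns: list[str],
    strategy: str = "median",
) -> FeatureTable:
    """Replace invalid zeros in named numeric columns by a column statistic.

    Zero is a recording artefact in many clinical columns (a living patient
    has no zero blood pressure). Zeros in ``columns`` are replaced by the
    ``median`` or ``min`` of that column's *non-zero* values. A column with
    no non-zero values is left unchanged with a warning.
    """
    if strategy not in ("median", "min"):
        raise ValueError(f"unknown strategy {strategy!r}; use 'median' or 'min'")
    X = table.X.copy()
    for col in columns:
        if col not in X.columns:
            raise KeyError(f"column {col!r} not in table")
        values = X[col].to_numpy()
        if not np.issubdtype(np.asarray(values).dtype, np.number):
            raise TypeError(f"column {col!r} is not numeric")
        nonzero = values[(values != 0) & ~pd.isna(values)]
        if nonzero.size == 0:
            warnings.warn(
                f"column {col!r} is entirely zero; statistic undefined, "
                "column left unmodified",
                UserWarning,
                stacklevel=2,
            )
            continue
        stat = float(np.median(nonzero)) if strategy == "median" else float(nonzero.min())
        X[col] = np.where(values == 0, stat, values)
    return FeatureTable(X, table.y.copy())


def _categorical_columns(X: pd.DataFrame) -> list[str]:
    return [
        c
        for c in X.columns
        if X[c].dtype == object
        or isinstance(X[c].dtype, pd.CategoricalDtype)
        or X[c].dtype == bool
    ]


def encode_and_impute(table: FeatureTable, fit_on: FeatureTable) -> FeatureTable:
    """One-hot encode categoricals and fill missing values.

    Vocabularies and imputation statistics come from ``fit_on`` (the
    training part). Numeric NaNs become the training median; categorical
    NaNs the training mode. Each categorical column expands, in place, to
    one indicator column per training-vocabulary level; a category unseen
    in training yields all-zero indicators.
    """
    cat_cols = _categorical_columns(fit_on.X)
    out_cols: dict[str, np.ndarray] = {}
    for col in table.X.columns:
        series = table.X[col]
        fit_series = fit_on.X[col]
        if col in cat_cols:
            mode = fit_series.mode(dropna=True)
            fill = mode.iloc[0] if len(mode) else ""
            series = series.fillna(fill)
            vocab = sorted(fit_series.dropna().unique().tolist(), key=str)
            for level in vocab:
                out_cols[f"{col}={level}"] = (series == level).astype(float).to_numpy()
        else:
            median = float(fit_series.median(skipna=True))
            out_cols[col] = series.fillna(median).astype(float).to_numpy()
    return FeatureTable(pd.DataFrame(out_cols), table.y.copy())


def normalize(table: FeatureTable, fit_on: FeatureTable) -> FeatureTable:
    """Min-max scale every column to [0, 1] with training min/max.

    Constant training columns map to 0; values outside the training range
    clip to the interval, so test rows can never leave [0, 1].
    """
    X = table.X.copy()
    for col in X.columns:
        lo = float(fit_on.X[col].min())
        hi = float(fit_on.X[col].max())
        span = hi - lo
        if span == 0:
            X[col] = 0.0
        else:
            X[col] = np.clip((X[col].to_numpy(dtype=float) - lo) / span, 0.0, 1.0)
    return FeatureTable(X, table.y.copy())


def stratified_split(
    table: FeatureTable,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DataSplit:
    """Partition a table into stratified train/val/test parts.

    The three fractions must be positive and sum to 1. Stratification keeps
    each part's class balance within rounding of the whole table's; the
    split is a deterministic function of (table, fractions, seed).
    """
    table.require_binary()
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0:
        raise ValueError(f"fractions must be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")

    idx = np.arange(table.n_instances)
    try:
        train_idx, rest_idx = train_test_split(
            idx,
            train_size=f_train,
            stratify=table.y,
            random_state=seed,
            shuffle=True,
        )
        val_idx, test_idx = train_test_split(
            rest_idx,
            train_size=f_val / (f_val + f_test),
            stratify=table.y[rest_idx],
            random_state=seed,
            shuffle=True,
        )
    except ValueError as exc:
        raise ValueError(
            "too few instances of one class to populate all three parts"
        ) from exc

    parts = {"train": np.sort(train_idx), "val": np.sort(val_idx), "test": np.sort(test_idx)}
    for name, part_idx in parts.items():
        classes = set(table.y[part_idx].tolist())
        if classes != {0, 1}:
            raise ValueError(
                f"{name} part is missing a class; too few minority instances"
            )
    split = DataSplit(
        train=table.take(parts["train"]),
        val=table.take(parts["val"]),
        test=table.take(parts["test"]),
        fractions=(f_train, f_val, f_test),
        seed=seed,
        indices=parts,
    )
    return split
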