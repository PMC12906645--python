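"""Tabular feature container used throughout the pipeline.

A :class:`FeatureTable` is a thin wrapper around a pandas DataFrame of
features plus a label vector. Labels are integer 0/1 after binarization;
tables loaded with a raw multi-class target keep the original labels until
:func:`gradvote.preprocess.binarize_target` is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "DataSplit", "load_table", "save_table"]


@dataclass
class FeatureTable:
    """Feature matrix (instances x features) with per-instance labels.

    Parameters
    ----------
    X
        Feature columns; numeric and/or categorical (object) dtype.
    y
        Label per instance. ``{0, 1}`` integers once binarized; raw labels
        are tolerated before binarization.
    """

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValueError(
                f"feature matrix has {len(self.X)} rows but {len(self.y)} labels"
            )

    @property
    def n_instances(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def is_binary(self) -> bool:
        vals = set(np.unique(self.y).tolist())
        return vals <= {0, 1}

    def require_binary(self) -> None:
        if not self.is_binary:
            raise ValueError(
                f"labels are not binary 0/1: found {sorted(set(self.y.tolist()))[:6]}"
            )

    @property
    def positive_fraction(self) -> float:
        self.require_binary()
        return float(np.mean(self.y == 1))

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.X.copy(), self.y.copy())

    def take(self, indices: np.ndarray) -> "FeatureTable":
        """Row subset by positional indices (index is reset)."""
        idx = np.asarray(indices)
        return FeatureTable(self.X.iloc[idx].reset_index(drop=True), self.y[idx])


@dataclass
class DataSplit:
    """Stratified three-way partition of a table into train/val/test."""

    train: FeatureTable
    val: FeatureTable
    test: FeatureTable
    fractions: tuple[float, float, float]
    seed: int
    indices: dict[str, np.ndarray] = field(default_factory=dict)

    def parts(self) -> dict[str, FeatureTable]:
        return {"train": self.train, "val": self.val, "test": self.test}

    def manifest(self) -> dict:
        """JSON-serializable record of which rows went where."""
        return {
            "fractions": list(self.fractions),
            "seed": self.seed,
            "indices": {k: np.asarray(v).tolist() for k, v in self.indices.items()},
        }


def load_table(
    path: str | Path,
    target_column: str,
    positive_label=None,
    positive_classes=None,
    delimiter: str = ",",
) -> FeatureTable:
    """Read a delimited text file with a header row into a FeatureTable.

    Exactly one binarization route applies:

    * ``positive_classes`` — any observed label in the set maps to 1, the
      rest to 0 (multi-class targets).
    * ``positive_label`` — requires a two-valued target; that value maps
      to 1, the other to 0.
    * neither — the target must already be coded 0/1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"data file not found: {path}")
    df = pd.read_csv(path, sep=delimiter)
    if target_column not in df.columns:
        raise KeyError(
            f"target column {target_column!r} not in header {list(df.columns)}"
        )
    target = df[target_column]
    X = df.drop(columns=[target_column])

    if positive_classes is not None:
        y = target.isin(list(positive_classes)).astype(int).to_numpy()
    elif positive_label is not None:
        distinct = pd.unique(target.dropna())
        if len(distinct) > 2:
            raise ValueError(
                f"target {target_column!r} has {len(distinct)} distinct values; "
                "supply positive_classes to binarize a multi-class target"
            )
        y = (target == positive_label).astype(int).to_numpy()
    else:
        y = target.to_numpy()
        if not set(pd.unique(target).tolist()) <= {0, 1}:
            raise ValueError(
                f"target {target_column!r} is not 0/1 coded; supply "
                "positive_label or positive_classes"
            )
        y = y.astype(int)
    return FeatureTable(X, y)


def save_table(
    table: FeatureTable,
    path: str | Path,
    target_column: str = "target",
    delimiter: str = ",",
) -> None:
    """Write features + target to a delimited text file with a header."""
    df = table.X.copy()
    df[target_column] = table.y
    df.to_csv(path, sep=delimiter, index=False)
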