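"""Seeded synthetic tabular data with clinical-dataset structure.

The generator emulates the statistical shape of public disease-screening
tables: a binary outcome with class imbalance anywhere from ~8% to ~53%
positives, a handful of informative numeric measurements, a few categorical
lifestyle/demographic columns, label noise, missing cells, and "invalid
zero" artefacts in designated numeric columns. It never copies any real
record; every value is drawn from a seeded generator so the same scenario
always reproduces the same table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatable import FeatureTable

__all__ = ["ScenarioSpec", "generate", "corrupt", "load_scenario"]

_CAT_LEVELS = ("a", "b", "c")


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic-data scenario.

    ``class_separation`` is the mean shift of each informative numeric
    feature between classes, in within-class standard-deviation units;
    0 means no signal, 3 means near-perfect separability. ``label_noise``,
    ``invalid_zero_rate`` and ``missing_rate`` are proportions in [0, 1].
    """

    n_instances: int = 1000
    n_numeric: int = 8
    n_categorical: int = 2
    positive_fraction: float = 0.35
    class_separation: float = 1.5
    label_noise: float = 0.02
    invalid_zero_rate: float = 0.0
    missing_rate: float = 0.0
    zero_columns: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("positive_fraction", "label_noise", "invalid_zero_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_instances <= 0 or self.n_numeric < 0 or self.n_categorical < 0:
            raise ValueError("counts must be positive")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def load_scenario(path: str | Path) -> ScenarioSpec:
    """Read a ScenarioSpec from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ScenarioSpec(**data)


def _cat_probs(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    # Class-0 baseline multinomial; class-1 tilted geometrically so the
    # signal vanishes when class_separation is 0.
    p0 = np.array([0.5, 0.3, 0.2])
    tilt = np.exp(0.5 * spec.class_separation * np.arange(len(p0)))
    p1 = p0 * tilt
    return p0, p1 / p1.sum()


def generate(spec: ScenarioSpec) -> FeatureTable:
    """Draw a seeded feature table matching a scenario.

    The positive-class count is exact — ``round(n * positive_fraction)``
    labels are 1 — so small tables hit extreme imbalance regimes without
    binomial jitter. Numeric features are class-conditionally Gaussian
    (unit variance, class-1 mean shifted by ``class_separation``, plus a
    per-feature baseline offset); categorical features are class-dependent
    multinomials. ``label_noise`` then flips an exact rounded fraction of
    labels — the same number from each class, so the marginal positive
    count stays exact — leaving features attached to the original class.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_instances
    n_pos = int(round(n * spec.positive_fraction))
    if n_pos == 0 or n_pos == n:
        raise ValueError(
            f"positive_fraction={spec.positive_fraction} yields a single-class "
            f"table at n={n}"
        )
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    y = y[rng.permutation(n)]

    cols: dict[str, np.ndarray] = {}
    for j in range(spec.n_numeric):
        baseline = 2.0 * j  # distinct location per measurement column
        shift = spec.class_separation
        cols[f"num{j}"] = baseline + rng.normal(size=n) + shift * y
    p0, p1 = _cat_probs(spec)
    levels = np.array(_CAT_LEVELS)
    for j in range(spec.n_categorical):
        draws0 = rng.choice(len(levels), size=n, p=p0)
        draws1 = rng.choice(len(levels), size=n, p=p1)
        cols[f"cat{j}"] = levels[np.where(y == 1, draws1, draws0)]

    # Balanced flips (k per class) keep the marginal positive count exact.
    k = int(round(n * spec.label_noise / 2))
    if k:
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        if k > min(len(pos_idx), len(neg_idx)):
            raise ValueError("label_noise too high for the minority class size")
        flip = np.concatenate(
            [rng.choice(pos_idx, size=k, replace=False),
             rng.choice(neg_idx, size=k, replace=False)]
        )
        y = y.copy()
        y[flip] = 1 - y[flip]
    return FeatureTable(pd.DataFrame(cols), y)


def corrupt(table: FeatureTable, spec: ScenarioSpec) -> FeatureTable:
    """Inject invalid zeros and missing cells into a table.

    Designated columns (``spec.zero_columns``, defaulting to the first
    numeric column) receive zeros in an exact rounded fraction of rows;
    random feature cells across the whole table are blanked at
    ``missing_rate``. Labels are never touched. Uses a corruption-specific
    seeded stream so generate+corrupt stays reproducible.
    """
    rng = np.random.default_rng([spec.seed, 7])
    X = table.X.copy()
    n = len(X)

    if spec.invalid_zero_rate > 0:
        numeric = [c for c in X.columns if np.issubdtype(X[c].dtype, np.number)]
        targets = spec.zero_columns if spec.zero_columns else numeric[:1]
        for col in targets:
            if col not in X.columns:
                raise KeyError(f"zero column {col!r} not in table")
            k = int(round(n * spec.invalid_zero_rate))
            rows = rng.choice(n, size=k, replace=False)
            vals = X[col].to_numpy(dtype=float, copy=True)
            vals[rows] = 0.0
            X[col] = vals

    if spec.missing_rate > 0:
        n_cells = n * X.shape[1]
        k = int(round(n_cells * spec.missing_rate))
        flat = rng.choice(n_cells, size=k, replace=False)
        for cell in flat:
            i, j = divmod(int(cell), X.shape[1])
            col = X.columns[j]
            if np.issubdtype(X[col].dtype, np.number):
                X.loc[i, col] = np.nan
            else:
                X.loc[i, col] = None
    return FeatureTable(X, table.y.copy())
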