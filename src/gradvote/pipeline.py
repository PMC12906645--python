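"""End-to-end pipeline stages and their run configuration.

Each stage reads the artifacts of the previous one from a common output
directory, so stages can be run individually (from the CLI) or chained by
:func:`run_all`. Layout under the output directory::

    data/raw.csv                      generate/ingest
    data/{train,val,test}.csv         preprocess (encoded + normalized)
    data/split_manifest.json
    models/<FAMILY>.joblib, models.json
    ensemble/results.csv              one row per subset
    ensemble/best.json                winning subset, weights, metrics
    ensemble/traces/<subset>.csv      per-iteration losses
    ensemble/metrics_{val,test}.json, roc_{val,test}.csv
    manifest.json                     full config echo (reproducibility)
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import base_models, preprocess, synthetic
from .base_models import BaseModelSpec, FAMILIES
from .datatable import DataSplit, FeatureTable, load_table, save_table
from .optimizer import WeightOptimizerConfig
from .search import results_to_frame, search
from .synthetic import ScenarioSpec

logger = logging.getLogger("gradvote")

__all__ = [
    "RunConfig",
    "run_generate",
    "run_preprocess",
    "run_tune",
    "run_search",
    "run_all",
]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to YAML/JSON."""

    # data source: either a synthetic scenario or a CSV on disk
    scenario: ScenarioSpec | None = None
    data_path: str | None = None
    target_column: str = "target"
    positive_label: object = None
    positive_classes: list | None = None
    delimiter: str = ","
    # preprocessing
    zero_columns: list[str] = field(default_factory=list)
    zero_strategy: str = "median"
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_seed: int = 0
    # base models
    families: tuple[str, ...] = FAMILIES
    grids: dict = field(default_factory=dict)
    k_folds: int = 5
    model_seed: int = 0
    # weight optimization + search
    optimizer: WeightOptimizerConfig = field(default_factory=WeightOptimizerConfig)
    selection: str = "validation"
    output_dir: str = "out"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "scenario" in data and data["scenario"] is not None:
            data["scenario"] = ScenarioSpec(**data["scenario"])
        if "optimizer" in data and isinstance(data["optimizer"], dict):
            data["optimizer"] = WeightOptimizerConfig(**data["optimizer"])
        if "fractions" in data:
            data["fractions"] = tuple(data["fractions"])
        if "families" in data:
            data["families"] = tuple(data["families"])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fractions"] = list(self.fractions)
        d["families"] = list(self.families)
        return d


def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_manifest(config: RunConfig) -> None:
    (_outdir(config) / "manifest.json").write_text(
        json.dumps(config.to_dict(), indent=2, default=str)
    )


def run_generate(config: RunConfig) -> Path:
    """Materialize the synthetic scenario as data/raw.csv (plus manifest)."""
    if config.scenario is None:
        raise ValueError("run_generate needs a synthetic scenario in the config")
    out = _outdir(config) / "data"
    out.mkdir(exist_ok=True)
    table = synthetic.generate(config.scenario)
    if config.scenario.invalid_zero_rate > 0 or config.scenario.missing_rate > 0:
        table = synthetic.corrupt(table, config.scenario)
    raw = out / "raw.csv"
    save_table(table, raw, target_column=config.target_column)
    _write_manifest(config)
    logger.info("generated %d x %d table -> %s", table.n_instances, table.n_features, raw)
    return raw


def _load_raw(config: RunConfig) -> FeatureTable:
    path = config.data_path or str(_outdir(config) / "data" / "raw.csv")
    return load_table(
        path,
        target_column=config.target_column,
        positive_label=config.positive_label,
        positive_classes=config.positive_classes,
        delimiter=config.delimiter,
    )


def run_preprocess(config: RunConfig) -> DataSplit:
    """Impute invalid zeros, split, then encode/impute/normalize per part."""
    out = _outdir(config) / "data"
    out.mkdir(exist_ok=True)
    table = _load_raw(config)
    if config.zero_columns:
        table = preprocess.impute_invalid_zeros(
            table, config.zero_columns, config.zero_strategy
        )
    split = preprocess.stratified_split(table, config.fractions, config.split_seed)
    train_raw = split.train
    parts = {}
    for name, part in split.parts().items():
        encoded = preprocess.encode_and_impute(part, fit_on=train_raw)
        parts[name] = encoded
    fit_encoded = parts["train"]
    for name in parts:
        parts[name] = preprocess.normalize(parts[name], fit_on=fit_encoded)
        save_table(parts[name], out / f"{name}.csv", target_column=config.target_column)
    (out / "split_manifest.json").write_text(json.dumps(split.manifest()))
    logger.info(
        "split %d instances into %s", table.n_instances,
        {k: v.n_instances for k, v in parts.items()},
    )
    return DataSplit(
        parts["train"], parts["val"], parts["test"],
        split.fractions, split.seed, split.indices,
    )


def _load_split(config: RunConfig) -> DataSplit:
    out = _outdir(config) / "data"
    manifest = json.loads((out / "split_manifest.json").read_text())
    tables = {
        name: load_table(out / f"{name}.csv", target_column=config.target_column)
        for name in ("train", "val", "test")
    }
    return DataSplit(
        tables["train"], tables["val"], tables["test"],
        tuple(manifest["fractions"]), manifest["seed"],
        {k: np.asarray(v) for k, v in manifest["indices"].items()},
    )


def run_tune(config: RunConfig, split: DataSplit | None = None):
    """Grid-search all configured base-model families on the training part."""
    split = split or _load_split(config)
    models = []
    for family in config.families:
        spec = BaseModelSpec(
            family=family,
            grid=config.grids.get(family),
            k_folds=config.k_folds,
            seed=config.model_seed,
        )
        fitted = base_models.tune(spec, split.train)
        logger.info(
            "%s: cv_accuracy=%.4f params=%s",
            family, fitted.cv_accuracy, fitted.chosen_hyperparameters,
        )
        models.append(fitted)
    base_models.save_models(models, _outdir(config) / "models")
    return models


def run_search(config: RunConfig, split: DataSplit | None = None, models=None):
    """Fit weights for every subset, write results/traces/best artifacts."""
    split = split or _load_split(config)
    if models is None:
        models = base_models.load_models(_outdir(config) / "models", config.families)
    best, results = search(models, split, config.optimizer, config.selection)

    ens_dir = _outdir(config) / "ensemble"
    traces_dir = ens_dir / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    results_to_frame(results).to_csv(ens_dir / "results.csv", index=False)
    for r in results:
        lines = ["iteration,train_loss,val_loss"] + [
            f"{t},{tr:.12g},{vl:.12g}"
            for t, (tr, vl) in enumerate(zip(r.trace.train_losses, r.trace.val_losses))
        ]
        (traces_dir / ("+".join(r.subset) + ".csv")).write_text("\n".join(lines) + "\n")

    best_payload = {
        "subset": list(best.subset),
        "weights": best.weights.tolist(),
        "selection": config.selection,
        "train_accuracy": best.train_accuracy,
        "val_accuracy": best.val_metrics.accuracy,
        "val_auc": best.val_metrics.auc,
        "test_accuracy": best.test_metrics.accuracy,
        "test_auc": best.test_metrics.auc,
        "best_val_loss": best.trace.best_loss,
        "iterations_run": best.trace.iterations_run,
        "stop_reason": best.trace.stop_reason,
        "init_seed": best.init_seed,
    }
    (ens_dir / "best.json").write_text(json.dumps(best_payload, indent=2))
    best.val_metrics.to_json(ens_dir / "metrics_val.json")
    best.test_metrics.to_json(ens_dir / "metrics_test.json")
    best.val_metrics.roc_to_csv(ens_dir / "roc_val.csv")
    best.test_metrics.roc_to_csv(ens_dir / "roc_test.csv")
    logger.info(
        "best subset %s: val acc=%.4f auc=%.4f | test acc=%.4f auc=%.4f",
        "+".join(best.subset),
        best.val_metrics.accuracy, best.val_metrics.auc,
        best.test_metrics.accuracy, best.test_metrics.auc,
    )
    return best, results


def run_all(config: RunConfig):
    """generate (if synthetic) -> preprocess -> tune -> search."""
    if config.scenario is not None and config.data_path is None:
        run_generate(config)
    else:
        _write_manifest(config)
    split = run_preprocess(config)
    models = run_tune(config, split)
    return run_search(config, split, models)
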