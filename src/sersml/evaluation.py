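"""Benchmark orchestration: RD vs FSD vs DAD across model families.

Three training conditions are compared under a two-fold train/test swap
(each half of a stratified 50/50 split serves once as training and once as
test, so every spectrum is predicted exactly once):

* **RD**  — preprocessed spectra only;
* **FSD** — RD plus the k-means feature mask;
* **DAD** — FSD plus noise + SMOTE training-pool augmentation.

The feature mask, the group noise model and all augmentation are fitted on
the training half of each fold only; held-out spectra never influence any
fitted component.  A config flag allows fitting the mask once on all data
for fidelity experiments, at the cost of leakage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .augmentation import AugmentationConfig, build_training_pool
from .classification import (
    FAMILIES,
    ModelSpec,
    PredictionSet,
    accuracy,
    confusion_matrix,
    predict_groups,
    split_train_test,
    tune_and_train,
)
from .dataset import SpectrumSet
from .feature_selection import KMeansShiftSelector, apply_mask
from .preprocessing import PreprocessConfig, preprocess_set

CONDITIONS: tuple[str, ...] = ("RD", "FSD", "DAD")


@dataclasses.dataclass
class BenchmarkConfig:
    families: tuple[str, ...] = FAMILIES
    conditions: tuple[str, ...] = CONDITIONS
    preset: str = "default"
    cv_folds: int = 5
    seed: int = 0
    k_max: int = 10
    n_drop: int = 1
    kmeans_n_init: int = 10
    elbow_n_init: int = 10
    noise_factor: int = 40
    smote_per_class: int = 100
    smote_k: int = 5
    refit_mask_per_fold: bool = True
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)

    def __post_init__(self) -> None:
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}; expected subset of {CONDITIONS}")


@dataclasses.dataclass
class CellResult:
    condition: str
    family: str
    accuracy: float | None
    per_analyte_accuracy: float | None
    confusion: np.ndarray | None  # pooled over both folds, rows = true group
    chosen_params: list[dict] = dataclasses.field(default_factory=list)  # per fold
    error: str | None = None


@dataclasses.dataclass
class EvaluationReport:
    cells: dict[tuple[str, str], CellResult]
    seed: int
    config: dict
    mask_summaries: list[dict]

    def accuracy_table(self) -> dict[str, dict[str, float | None]]:
        table: dict[str, dict[str, float | None]] = {}
        for (cond, fam), cell in self.cells.items():
            table.setdefault(cond, {})[fam] = cell.accuracy
        return table

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "mask_summaries": self.mask_summaries,
            "cells": [
                {
                    "condition": c.condition,
                    "family": c.family,
                    "accuracy": c.accuracy,
                    "per_analyte_accuracy": c.per_analyte_accuracy,
                    "confusion": None if c.confusion is None else c.confusion.tolist(),
                    "chosen_params": [_jsonable(p) for p in c.chosen_params],
                    "error": c.error,
                }
                for c in self.cells.values()
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _jsonable(params: dict) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()}


def _fold_data(dataset: SpectrumSet, config: BenchmarkConfig):
    """Preprocess, split, and fit per-fold masks and augmented pools once.

    Returns a list of two fold dicts, each holding train/test sets for every
    requested condition, so model families can reuse them.
    """
    pre = preprocess_set(dataset, config.preprocess)
    train_a, test_b = split_train_test(pre, seed=config.seed)
    folds = []
    need_mask = any(c in config.conditions for c in ("FSD", "DAD"))
    shared_selector = None
    if need_mask and not config.refit_mask_per_fold:
        shared_selector = KMeansShiftSelector(
            k_max=config.k_max,
            n_drop=config.n_drop,
            n_init=config.kmeans_n_init,
            elbow_n_init=config.elbow_n_init,
            random_state=config.seed,
            shifts=pre.shifts,
        ).fit(pre.intensities, pre.y)
    for fold_id, (train, test) in enumerate([(train_a, test_b), (test_b, train_a)]):
        fold: dict = {"fold_id": fold_id, "RD": (train, test)}
        if need_mask:
            if shared_selector is None:
                selector = KMeansShiftSelector(
                    k_max=config.k_max,
                    n_drop=config.n_drop,
                    n_init=config.kmeans_n_init,
                    elbow_n_init=config.elbow_n_init,
                    random_state=config.seed,
                    shifts=pre.shifts,
                ).fit(train.intensities, train.y)
            else:
                selector = shared_selector
            mask = selector.mask_
            fold["mask"] = mask
            train_m, test_m = apply_mask(train, mask), apply_mask(test, mask)
            fold["FSD"] = (train_m, test_m)
            if "DAD" in config.conditions:
                pool = build_training_pool(
                    train_m,
                    AugmentationConfig(
                        noise_factor=config.noise_factor,
                        smote_per_class=config.smote_per_class,
                        smote_k=config.smote_k,
                        seed=config.seed + fold_id,
                    ),
                )
                fold["DAD"] = (pool, test_m)
        folds.append(fold)
    return folds


def _evaluate_cell(
    folds, condition: str, spec: ModelSpec
) -> tuple[PredictionSet, list[dict]]:
    preds: list[PredictionSet] = []
    params: list[dict] = []
    for fold in folds:
        train, test = fold[condition]
        model = tune_and_train(spec, train.intensities, train.y)
        preds.append(predict_groups(model, test))
        params.append(model.params)
    pooled = PredictionSet(
        y_true=np.concatenate([p.y_true for p in preds]),
        y_pred=np.concatenate([p.y_pred for p in preds]),
    )
    return pooled, params


def run_condition(
    dataset: SpectrumSet,
    condition: str,
    spec: ModelSpec,
    config: BenchmarkConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Pooled swap-fold accuracy and confusion for one condition and family."""
    config = config or BenchmarkConfig()
    config = dataclasses.replace(config, conditions=(condition,), families=(spec.family,))
    folds = _fold_data(dataset, config)
    pooled, _ = _evaluate_cell(folds, condition, spec)
    return accuracy(pooled), confusion_matrix(pooled)


def run_benchmark(
    dataset: SpectrumSet,
    families: Sequence[str] | None = None,
    config: BenchmarkConfig | None = None,
) -> EvaluationReport:
    """Full conditions-by-families benchmark with per-cell failure isolation."""
    config = config or BenchmarkConfig()
    families = tuple(families) if families is not None else config.families
    folds = _fold_data(dataset, config)
    mask_summaries = [
        {
            "fold": f["fold_id"],
            "k": int(f["mask"].assignment.k),
            "dropped_clusters": list(f["mask"].dropped_clusters),
            "n_selected": int(f["mask"].selected_idx.size),
        }
        for f in folds
        if "mask" in f
    ]
    cells: dict[tuple[str, str], CellResult] = {}
    for condition in config.conditions:
        for family in families:
            spec = ModelSpec(
                family, preset=config.preset, cv_folds=config.cv_folds, seed=config.seed
            )
            try:
                pooled, params = _evaluate_cell(folds, condition, spec)
                cells[(condition, family)] = CellResult(
                    condition=condition,
                    family=family,
                    accuracy=accuracy(pooled, "group"),
                    per_analyte_accuracy=accuracy(pooled, "per_analyte"),
                    confusion=confusion_matrix(pooled),
                    chosen_params=params,
                )
            except Exception as exc:  # isolate one diverging family
                cells[(condition, family)] = CellResult(
                    condition=condition,
                    family=family,
                    accuracy=None,
                    per_analyte_accuracy=None,
                    confusion=None,
                    error=f"{type(exc).__name__}: {exc}",
                )
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["families"] = list(families)
    return EvaluationReport(
        cells=cells, seed=config.seed, config=cfg_dict, mask_summaries=mask_summaries
    )


def summarize_errors(report: EvaluationReport) -> dict:
    """Per-group misclassification rates per cell, and each cell's worst group."""
    out: dict = {}
    for (cond, fam), cell in report.cells.items():
        if cell.confusion is None:
            continue
        cm = cell.confusion
        row_sums = cm.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            err = 1.0 - np.where(row_sums > 0, np.diag(cm) / row_sums, np.nan)
        worst = int(np.nanargmax(err)) + 1  # group ids are 1-based
        out[f"{cond}/{fam}"] = {
            "error_rates": {g + 1: float(err[g]) for g in range(cm.shape[0])},
            "worst_group": worst,
        }
    return out
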