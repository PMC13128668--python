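"""Grid enumeration, stratified k-fold cross-validation, model selection.

The default grid spans the eight tuned hyperparameters — kernel size
(7, 9), filters (8, 16), dense layers (1, 2, 3), units (512, 1024 or the
input dimension), dropout (0.1, 0.2), learning rate (1e-3, 1e-5), max
epochs (10, 20, 30) and batch size (32, 64, 128) — 1,296 configurations
in all. Each candidate is scored by its mean Matthews correlation
coefficient over stratified folds (feature processing refit per fold);
the argmax wins, ties broken by enumeration order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .descriptors import DescriptorGroup
from .metrics import METRIC_NAMES, MetricReport
from .model import HalfLifeModel, ModelConfig

#: documented axis order for enumeration
AXES = (
    "kernel_size",
    "n_filters",
    "n_layers",
    "n_units",
    "dropout",
    "learning_rate",
    "max_epochs",
    "batch_size",
)


@dataclass(frozen=True)
class HyperparameterGrid:
    kernel_size: tuple = (7, 9)
    n_filters: tuple = (8, 16)
    n_layers: tuple = (1, 2, 3)
    n_units: tuple = (512, 1024, "input_dim")
    dropout: tuple = (0.1, 0.2)
    learning_rate: tuple = (1e-3, 1e-5)
    max_epochs: tuple = (10, 20, 30)
    batch_size: tuple = (32, 64, 128)

    def size(self) -> int:
        out = 1
        for axis in AXES:
            out *= len(getattr(self, axis))
        return out

    @classmethod
    def from_json(cls, path: str | Path) -> "HyperparameterGrid":
        d = json.loads(Path(path).read_text())
        return cls(**{k: tuple(v) for k, v in d.items()})


DEFAULT_GRID = HyperparameterGrid()

#: reduced grid exercising the same code paths at desk scale (8 configs)
REDUCED_GRID = HyperparameterGrid(
    kernel_size=(7,),
    n_filters=(8,),
    n_layers=(1, 2),
    n_units=("input_dim",),
    dropout=(0.1, 0.2),
    learning_rate=(1e-3,),
    max_epochs=(10,),
    batch_size=(32, 64),
)


def enumerate_grid(
    grid: HyperparameterGrid = DEFAULT_GRID, seed: int = 0, patience: int = 5
) -> list[ModelConfig]:
    """All configurations in lexicographic order over the documented axes."""
    values = []
    for axis in AXES:
        axis_vals = getattr(grid, axis)
        if len(axis_vals) == 0:
            raise ValueError(f"empty grid axis {axis}")
        values.append(axis_vals)
    configs = []
    idx = [0] * len(AXES)
    while True:
        kwargs = {axis: values[i][idx[i]] for i, axis in enumerate(AXES)}
        configs.append(ModelConfig(seed=seed, patience=patience, **kwargs))
        for i in reversed(range(len(AXES))):
            idx[i] += 1
            if idx[i] < len(values[i]):
                break
            idx[i] = 0
        else:
            break
    return configs


def kfold_split(
    labels: np.ndarray, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold index pairs; every sample validates exactly once."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(y) < k:
        raise ValueError(f"n={len(y)} < k={k}")
    counts = np.bincount(y.astype(int))
    if counts.min() < k:
        import warnings

        warnings.warn(
            f"minority class has {counts.min()} < k={k} samples; some "
            "validation folds will hold 0 or 1 of it",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(y)), y)]


@dataclass
class CVResult:
    config: ModelConfig
    fold_reports: list[MetricReport]
    enumeration_index: int = 0
    failure: str | None = None

    def mean(self, metric: str = "MCC") -> float:
        vals = [r.as_dict()[metric] for r in self.fold_reports]
        return float(np.mean(vals))

    def stderr(self, metric: str = "MCC") -> float:
        vals = [r.as_dict()[metric] for r in self.fold_reports]
        if len(vals) < 2:
            return float("nan")
        return float(np.std(vals, ddof=1) / np.sqrt(len(vals)))


def cross_validate(
    model: HalfLifeModel,
    config: ModelConfig,
    k: int = 10,
    seed: int = 0,
    exclude_groups: Iterable[DescriptorGroup] = (),
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVResult:
    """Refit features and train a fresh network per fold; aggregate metrics.

    ``folds`` may be supplied so every configuration (and every ablation
    condition) is compared on identical splits.
    """
    if folds is None:
        folds = kfold_split(model.y, k=k, seed=seed)
    reports = []
    for train_idx, val_idx in folds:
        res = model.fit_on_split(config, train_idx, val_idx, exclude_groups)
        reports.append(res.validation_report())
    return CVResult(config, reports)


def grid_search(
    model: HalfLifeModel,
    grid: HyperparameterGrid = REDUCED_GRID,
    k: int = 10,
    seed: int = 0,
    exclude_groups: Iterable[DescriptorGroup] = (),
) -> list[CVResult]:
    """Cross-validate every configuration on one shared set of folds."""
    folds = kfold_split(model.y, k=k, seed=seed)
    results = []
    for i, config in enumerate(enumerate_grid(grid, seed=seed)):
        try:
            cv = cross_validate(model, config, folds=folds)
        except (FloatingPointError, ValueError) as exc:
            cv = CVResult(config, [], failure=str(exc))
        cv.enumeration_index = i
        results.append(cv)
    return results


def select_best(cv_results: Sequence[CVResult]) -> CVResult:
    """Highest mean MCC wins; exact ties go to the earlier-enumerated config."""
    ok = [r for r in cv_results if not r.failure and r.fold_reports]
    if not ok:
        raise ValueError("no successful configurations to select from")
    return max(
        sorted(ok, key=lambda r: r.enumeration_index),
        key=lambda r: (r.mean("MCC"), -r.enumeration_index),
    )


def report_frame(cv_results: Sequence[CVResult]) -> pd.DataFrame:
    """Grid-search report: one row per configuration, ranked by mean MCC."""
    rows = []
    for r in cv_results:
        row = {axis: getattr(r.config, axis) for axis in AXES}
        row["enumeration_index"] = r.enumeration_index
        if r.failure:
            row["failure"] = r.failure
        else:
            for m in METRIC_NAMES:
                row[f"mean_{m}"] = r.mean(m)
                row[f"se_{m}"] = r.stderr(m)
        rows.append(row)
    df = pd.DataFrame(rows)
    if "mean_MCC" in df:
        df["rank"] = df["mean_MCC"].rank(ascending=False, method="min")
    return df
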