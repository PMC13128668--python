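"""Leave-one-group-out ablation of the physicochemical descriptor groups.

Each condition removes one descriptor group's columns (or all four)
before feature processing and re-runs cross-validation with the same base
configuration, folds and seed as the baseline; hyperparameters are not
re-searched, and a ``n_units='input_dim'`` configuration re-resolves to
the reduced width automatically. Embeddings always remain in the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .descriptors import DescriptorGroup
from .model import HalfLifeModel, ModelConfig
from .selection import CVResult, cross_validate, kfold_split

ALL_GROUPS = tuple(DescriptorGroup)


@dataclass(frozen=True)
class AblationPlan:
    """Exclusion sets to evaluate; condition 0 is always the full model."""

    conditions: tuple[frozenset[DescriptorGroup], ...] = (
        frozenset(),
        frozenset({DescriptorGroup.GAPPED_KMER}),
        frozenset({DescriptorGroup.GROUPED_COMPOSITION}),
        frozenset({DescriptorGroup.PHYSCHEM_PROPERTY}),
        frozenset({DescriptorGroup.SEQUENCE_ORDER}),
        frozenset(ALL_GROUPS),
    )

    def __post_init__(self) -> None:
        if not self.conditions or self.conditions[0] != frozenset():
            raise ValueError("condition 0 must be the empty exclusion (baseline)")


def condition_label(excluded: frozenset[DescriptorGroup]) -> str:
    if not excluded:
        return "no_exclusion"
    if set(excluded) == set(ALL_GROUPS):
        return "all_groups"
    return "+".join(sorted(g.value for g in excluded))


@dataclass
class AblationReport:
    results: list[tuple[frozenset[DescriptorGroup], CVResult]]

    @property
    def baseline(self) -> CVResult:
        return self.results[0][1]

    def mcc(self, excluded: frozenset[DescriptorGroup]) -> float:
        for cond, cv in self.results:
            if cond == excluded:
                return cv.mean("MCC")
        raise KeyError(condition_label(excluded))


def run_ablation(
    model: HalfLifeModel,
    base_config: ModelConfig,
    plan: AblationPlan = AblationPlan(),
    k: int = 10,
    seed: int = 0,
) -> AblationReport:
    """Cross-validate every exclusion condition on identical folds."""
    folds = kfold_split(model.y, k=k, seed=seed)
    results = []
    for excluded in plan.conditions:
        cv = cross_validate(
            model, base_config, folds=folds, exclude_groups=tuple(excluded)
        )
        results.append((excluded, cv))
    return AblationReport(results)


def format_report(report: AblationReport) -> pd.DataFrame:
    """Tabular view: condition, mean MCC, SE, delta vs baseline.

    Rows are sorted by delta MCC ascending, so the most damaging
    exclusion comes first; the baseline row has delta 0.
    """
    base = report.baseline.mean("MCC")
    rows = []
    for excluded, cv in report.results:
        rows.append(
            {
                "condition": condition_label(excluded),
                "mean_MCC": cv.mean("MCC"),
                "se_MCC": cv.stderr("MCC"),
                "delta_MCC": cv.mean("MCC") - base,
            }
        )
    return pd.DataFrame(rows).sort_values("delta_MCC", kind="stable").reset_index(drop=True)
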