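"""Model/Results interface for the word-beauty classification study.

:class:`WordBeautyModel` bundles a :class:`~wordbeauty.dataset.BeautyDataset`
with classifier hyperparameters; ``fit()`` runs the full study — train-on-all
confusion matrix, stratified k-fold ROC/AUC, impurity-based feature
importances, label-permutation null, per-feature one-way ANOVAs and the
pairwise-R² table — and returns a :class:`WordBeautyResults` carrying the
estimates plus a formatted ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import BeautyDataset
from .features import FEATURE_NAMES, FeatureContext
from .pipeline import ClassifierParams, EvaluationReport, evaluate
from .stats import anova_table, group_summary, pairwise_r2_table

__all__ = ["WordBeautyModel", "WordBeautyResults"]


class WordBeautyModel:
    """The eight-feature beautiful/ugly classification study.

    Parameters
    ----------
    dataset
        Labeled words with the 8-column feature matrix.
    params
        ERT hyperparameters; defaults to parameter set 1 (100 trees,
        √8 features per split, unbounded depth).
    """

    def __init__(self, dataset: BeautyDataset, params: ClassifierParams | None = None):
        self.dataset = dataset
        self.params = params or ClassifierParams.set1()

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, params: ClassifierParams | None = None
    ) -> "WordBeautyModel":
        """Build from a featurized frame (word index, 8 features, ``label``)."""
        return cls(BeautyDataset.from_dataframe(df), params)

    @classmethod
    def from_targets(
        cls,
        labeled_targets,
        ctx: FeatureContext,
        params: ClassifierParams | None = None,
    ) -> "WordBeautyModel":
        """Featurize labeled target words against the resources, then build."""
        return cls(BeautyDataset.from_targets(labeled_targets, ctx), params)

    def fit(
        self, k: int = 5, n_permutation_runs: int = 5, seed: int = 0
    ) -> "WordBeautyResults":
        """Run the classification study and the statistical follow-ups."""
        report = evaluate(
            self.dataset,
            self.params,
            k=k,
            n_permutation_runs=n_permutation_runs,
            seed=seed,
        )
        return WordBeautyResults(self, report)


class WordBeautyResults:
    """Fitted study results: classifier evaluation plus per-feature stats."""

    def __init__(self, model: WordBeautyModel, report: EvaluationReport):
        self.model = model
        self.report = report
        ds = model.dataset
        self.anova = anova_table(ds, scale="z")
        self.anova_raw = anova_table(ds, scale="raw")
        self.pairwise_r2 = pairwise_r2_table(ds)
        self.group_summary = group_summary(ds)

    # -- convenience accessors -------------------------------------------
    @property
    def mean_auc(self) -> float:
        return self.report.mean_auc

    @property
    def fold_aucs(self) -> list[float]:
        return self.report.fold_aucs

    @property
    def importances(self) -> pd.Series:
        return self.report.importances

    @property
    def confusion_train(self) -> np.ndarray:
        return self.report.confusion_train

    @property
    def permutation_aucs(self) -> list[float]:
        return self.report.permutation_aucs

    @property
    def mean_permutation_auc(self) -> float:
        return float(np.mean(self.report.permutation_aucs))

    def to_dict(self) -> dict:
        out = self.report.to_dict()
        out["anova_z"] = self.anova.to_dict(orient="records")
        out["anova_raw"] = self.anova_raw.to_dict(orient="records")
        out["pairwise_r2"] = self.pairwise_r2.round(6).to_dict()
        out["group_summary"] = self.group_summary.round(6).reset_index().to_dict(
            orient="records"
        )
        out["note"] = "ANOVA p-values are raw; no multiple-testing correction applied."
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    def summary(self) -> str:
        """Human-readable study summary table."""
        rep = self.report
        p = rep.params
        lines = [
            "Word beauty classification study",
            "=" * 64,
            f"Words: {rep.n_words} "
            f"(beautiful {rep.group_sizes['beautiful']}, ugly {rep.group_sizes['ugly']})",
            f"Classifier: extremely randomized trees, {p.n_trees} trees, "
            f"features/split={p.features_per_split}, depth={p.max_depth or 'unbounded'} "
            f"[{p.set_name}]",
            f"Evaluation: stratified {rep.k}-fold CV, master seed {rep.seed}",
            "",
            "Confusion matrix (train = test; rows true, cols predicted; b/u):",
            f"  [[{rep.confusion_train[0, 0]:4d} {rep.confusion_train[0, 1]:4d}]",
            f"   [{rep.confusion_train[1, 0]:4d} {rep.confusion_train[1, 1]:4d}]]",
            "",
            f"Cross-validated AUC: mean {rep.mean_auc:.3f} "
            f"(folds: {', '.join(f'{a:.3f}' for a in rep.fold_aucs)})",
            f"Permutation null ({len(rep.permutation_aucs)} runs): "
            f"mean AUC {self.mean_permutation_auc:.3f} "
            f"(runs: {', '.join(f'{a:.3f}' for a in rep.permutation_aucs)})",
            "",
            "Feature importances (descriptive ranking):",
        ]
        for name, value in rep.importances.items():
            lines.append(f"  {name:<15s} {value:.3f}")
        lines += ["", "Per-feature one-way ANOVA (z-scored; raw p-values, uncorrected):"]
        lines.append(
            f"  {'feature':<15s} {'F':>7s} {'p':>9s} {'R2adj':>7s} "
            f"{'z-mean(b)':>10s} {'z-mean(u)':>10s}"
        )
        for _, row in self.anova.iterrows():
            lines.append(
                f"  {row['feature']:<15s} {row['F']:7.2f} {row['p']:9.4g} "
                f"{row['R2_adj']:7.3f} {row['mean_beautiful']:10.3f} {row['mean_ugly']:10.3f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<WordBeautyResults n={self.report.n_words} "
            f"mean_auc={self.mean_auc:.3f} params={self.report.params.set_name}>"
        )
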