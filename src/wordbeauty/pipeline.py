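"""Classification study: extremely randomized trees, CV, permutation null.

The study trains an extremely-randomized-trees (ERT) ensemble on the eight
QNA features and evaluates it three ways, mirroring the published design:

1. a train-on-all confusion matrix (with unbounded depth and distinct
   feature rows this is flawless by construction — a sanity check, not a
   performance estimate);
2. stratified k-fold cross-validated ROC/AUC from held-out probability
   scores;
3. a label-permutation null: shuffle the beautiful/ugly labels, rerun the
   cross-validation, and confirm the mean AUC sits at chance (0.5).

Classification uses the raw (non-z-scored) features — trees are invariant
to monotone per-feature rescaling — while the z-scored view feeds the
statistical follow-ups.  Probability scores are the fraction of trees
voting "beautiful".  One master seed fans out to fold assignment, tree
construction and permutations via independent numpy seed-sequence streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold

from .dataset import BeautyDataset
from .features import FEATURE_NAMES

__all__ = [
    "ClassifierParams",
    "EvaluationReport",
    "train_ensemble",
    "feature_importances",
    "stratified_kfold_auc",
    "permutation_test",
]

_MAX_SEED = 2**31 - 1


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from a master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % _MAX_SEED]


@dataclass(frozen=True)
class ClassifierParams:
    """ERT hyperparameters.

    Two named defaults are provided: ``set1`` (100 trees, √8 ≈ 3 features
    per split) and ``set2`` (1000 trees, all 8 features per split), both
    with unbounded depth.
    """

    n_trees: int = 100
    features_per_split: int | str = "sqrt"
    max_depth: int | None = None
    set_name: str = "set1"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if isinstance(self.features_per_split, int) and not (
            1 <= self.features_per_split <= len(FEATURE_NAMES)
        ):
            raise ValueError("features_per_split must be between 1 and 8")

    @classmethod
    def set1(cls) -> "ClassifierParams":
        return cls(n_trees=100, features_per_split="sqrt", set_name="set1")

    @classmethod
    def set2(cls) -> "ClassifierParams":
        return cls(n_trees=1000, features_per_split=len(FEATURE_NAMES), set_name="set2")

    @classmethod
    def named(cls, name: str) -> "ClassifierParams":
        try:
            return {"set1": cls.set1, "set2": cls.set2}[name]()
        except KeyError:
            raise ValueError(f"unknown parameter set {name!r}; use 'set1' or 'set2'") from None

    def build(self, seed: int) -> ExtraTreesClassifier:
        return ExtraTreesClassifier(
            n_estimators=self.n_trees,
            max_features=self.features_per_split,
            max_depth=self.max_depth,
            bootstrap=False,
            random_state=seed,
        )


def train_ensemble(ds: BeautyDataset, params: ClassifierParams, seed: int = 0):
    """Fit an ERT ensemble on the full dataset; deterministic under ``seed``."""
    clf = params.build(seed)
    clf.fit(ds.features.to_numpy(), ds.labels)
    return clf


def feature_importances(ensemble) -> pd.Series:
    """Mean impurity-decrease importances, normalized to sum 1, ranked.

    Returned sorted descending; the order is the descriptive predictor
    ranking, not an inferential statement.
    """
    if not hasattr(ensemble, "feature_importances_") or not hasattr(ensemble, "estimators_"):
        raise ValueError("ensemble is not fitted")
    imp = pd.Series(ensemble.feature_importances_, index=list(FEATURE_NAMES))
    return imp.sort_values(ascending=False)


def stratified_kfold_auc(
    ds: BeautyDataset,
    params: ClassifierParams,
    k: int = 5,
    seed: int = 0,
    labels: np.ndarray | None = None,
) -> tuple[list[float], float, list[tuple[np.ndarray, np.ndarray]]]:
    """Stratified k-fold cross-validated ROC/AUC.

    Folds preserve the beautiful/ugly proportion to within one item.  Each
    fold's ROC is swept over the held-out probability scores (trapezoidal
    AUC).  Returns ``(fold_aucs, mean_auc, fold_rocs)`` with each ROC a
    ``(fpr, tpr)`` pair.  ``labels`` overrides the dataset labels (used by
    the permutation test).
    """
    y = ds.labels if labels is None else np.asarray(labels, dtype=int)
    X = ds.features.to_numpy()
    if k < 2:
        raise ValueError("k must be >= 2")
    min_class = min(np.bincount(y))
    if k > min_class:
        raise ValueError(f"k={k} exceeds the smaller class count ({min_class})")
    fold_seed, tree_seed = _spawn_seeds(seed, 2)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
    fold_aucs: list[float] = []
    fold_rocs: list[tuple[np.ndarray, np.ndarray]] = []
    for i, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        clf = params.build(tree_seed + i)
        clf.fit(X[train_idx], y[train_idx])
        scores = clf.predict_proba(X[test_idx])[:, list(clf.classes_).index(1)]
        fpr, tpr, _ = roc_curve(y[test_idx], scores)
        fold_rocs.append((fpr, tpr))
        fold_aucs.append(float(auc(fpr, tpr)))
    return fold_aucs, float(np.mean(fold_aucs)), fold_rocs


def permutation_test(
    ds: BeautyDataset,
    params: ClassifierParams,
    k: int = 5,
    n_runs: int = 5,
    seed: int = 0,
) -> list[float]:
    """Label-shuffling null for the cross-validated AUC.

    For each run the beautiful/ugly labels are randomly permuted (a
    permutation identical to the original labeling is redrawn, so the null
    never evaluates the true assignment) and the stratified k-fold mean AUC
    recomputed.  Returns the per-run mean AUCs; with informative features
    removed this way the expectation is chance level, AUC = 0.5.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    perm_seed, *run_seeds = _spawn_seeds(seed, n_runs + 1)
    rng = np.random.default_rng(perm_seed)
    out: list[float] = []
    for r in range(n_runs):
        permuted = rng.permutation(ds.labels)
        while np.array_equal(permuted, ds.labels):
            permuted = rng.permutation(ds.labels)
        _, mean_auc, _ = stratified_kfold_auc(ds, params, k=k, seed=run_seeds[r], labels=permuted)
        out.append(mean_auc)
    return out


@dataclass
class EvaluationReport:
    """Bundled outputs of the classification study plus full provenance."""

    params: ClassifierParams
    k: int
    seed: int
    n_words: int
    group_sizes: dict[str, int]
    confusion_train: np.ndarray
    fold_aucs: list[float]
    mean_auc: float
    fold_rocs: list[tuple[np.ndarray, np.ndarray]]
    importances: pd.Series
    permutation_aucs: list[float]

    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "k": self.k,
            "seed": self.seed,
            "n_words": self.n_words,
            "group_sizes": self.group_sizes,
            "confusion_train": self.confusion_train.tolist(),
            "fold_aucs": self.fold_aucs,
            "mean_auc": self.mean_auc,
            "importances": self.importances.to_dict(),
            "permutation_aucs": self.permutation_aucs,
            "mean_permutation_auc": float(np.mean(self.permutation_aucs))
            if self.permutation_aucs
            else None,
        }

    def roc_table(self) -> pd.DataFrame:
        rows = []
        for fold, (fpr, tpr) in enumerate(self.fold_rocs):
            for f, t in zip(fpr, tpr):
                rows.append({"fold": fold, "fpr": float(f), "tpr": float(t)})
        return pd.DataFrame(rows)


def evaluate(
    ds: BeautyDataset,
    params: ClassifierParams | None = None,
    k: int = 5,
    n_permutation_runs: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Run the full classification study on a dataset.

    Train-on-all confusion matrix, stratified k-fold ROC/AUC, impurity
    importances and the label-permutation null, all derived from one master
    seed via independent streams.
    """
    params = params or ClassifierParams.set1()
    train_seed, cv_seed, perm_seed = _spawn_seeds(seed, 3)
    ensemble = train_ensemble(ds, params, seed=train_seed)
    predictions = ensemble.predict(ds.features.to_numpy())
    confusion = confusion_matrix(ds.labels, predictions, labels=[1, 0])
    fold_aucs, mean_auc, fold_rocs = stratified_kfold_auc(ds, params, k=k, seed=cv_seed)
    perm = permutation_test(ds, params, k=k, n_runs=n_permutation_runs, seed=perm_seed)
    return EvaluationReport(
        params=params,
        k=k,
        seed=seed,
        n_words=ds.n_words,
        group_sizes=ds.group_sizes,
        confusion_train=confusion,
        fold_aucs=fold_aucs,
        mean_auc=mean_auc,
        fold_rocs=fold_rocs,
        importances=feature_importances(ensemble),
        permutation_aucs=perm,
    )
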