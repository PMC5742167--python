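"""The labeled study dataset: words, binary beauty labels, feature matrix.

Labels are coded beautiful = 1, ugly = 0.  The z-scored view standardizes
each feature column over the pooled sample (mean 0, sample SD 1 with
denominator n−1), which is the scale on which the group contrasts of the
statistical follow-ups are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureContext, featurize_dataset

__all__ = ["BeautyDataset", "zscore_columns"]

LABEL_NAMES = {1: "beautiful", 0: "ugly"}


def zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-standardize a feature matrix (mean 0, sample SD 1, ddof=1).

    A constant column cannot be standardized and is rejected with the
    feature named, since a zero-variance predictor is a sign of a degenerate
    resource or generator configuration.
    """
    if len(matrix) < 2:
        raise ValueError("z-scoring needs at least two rows")
    sd = matrix.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        raise ValueError(f"constant feature column(s), cannot z-score: {constant}")
    return (matrix - matrix.mean()) / sd


@dataclass
class BeautyDataset:
    """Words with binary beautiful(1)/ugly(0) labels and their 8 features."""

    words: tuple[str, ...]
    labels: np.ndarray
    features: pd.DataFrame
    z_features: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if set(np.unique(self.labels)) != {0, 1}:
            raise ValueError("dataset must contain both beautiful (1) and ugly (0) words")
        if len(self.words) != len(self.labels) or len(self.words) != len(self.features):
            raise ValueError("words, labels and feature rows must align")
        missing = [c for c in FEATURE_NAMES if c not in self.features.columns]
        if missing:
            raise ValueError(f"feature matrix lacks columns: {missing}")
        self.features = self.features.loc[:, list(FEATURE_NAMES)].astype(float)
        self.z_features = zscore_columns(self.features)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BeautyDataset":
        """Build from a featurized frame (word index, 8 features, ``label``)."""
        words = tuple(df.index.astype(str))
        return cls(words, df["label"].to_numpy(), df[list(FEATURE_NAMES)].copy())

    @classmethod
    def from_targets(
        cls, labeled_targets: Sequence[tuple[str, int]], ctx: FeatureContext
    ) -> "BeautyDataset":
        """Featurize labeled targets and wrap the result."""
        return cls.from_dataframe(featurize_dataset(labeled_targets, ctx))

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            "beautiful": int((self.labels == 1).sum()),
            "ugly": int((self.labels == 0).sum()),
        }

    def to_csv(self, path) -> None:
        out = self.features.copy()
        out["label"] = self.labels
        out.to_csv(path, index_label="word")

    @classmethod
    def from_csv(cls, path) -> "BeautyDataset":
        return cls.from_dataframe(pd.read_csv(path, index_col="word"))
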