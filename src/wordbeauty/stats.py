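"""Per-feature statistical follow-ups: one-way ANOVA, pairwise R², summaries.

The classifier's descriptive importance ranking is complemented by
classical per-feature tests: a one-way ANOVA of each feature against the
beautiful/ugly grouping (with R² and adjusted R² as effect sizes), squared
Pearson correlations between feature pairs, and raw- and z-scale group
summary tables.  For a binary grouping the one-way ANOVA is algebraically
identical to a simple linear regression on the group indicator (F = t²),
so a single code path serves both framings.

No multiple-testing correction is applied across the eight features; the
p-values are raw and reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import BeautyDataset
from .features import FEATURE_NAMES

__all__ = ["AnovaResult", "one_way_anova", "pairwise_r2", "group_summary", "anova_table"]


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA decomposition with R² effect sizes."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    r2: float
    r2_adj: float
    group_means: tuple[float, ...]
    group_sizes: tuple[int, ...]

    def __str__(self) -> str:
        return (
            f"F({self.df_between}, {self.df_within}) = {self.f_stat:.2f}, "
            f"p = {self.p_value:.4g}, R² = {self.r2:.3f}, R²adj = {self.r2_adj:.3f}"
        )


def one_way_anova(values, groups) -> AnovaResult:
    """One-way ANOVA of ``values`` across the levels of ``groups``.

    Decomposes SS_total = SS_between + SS_within;
    F = (SS_b/df_b) / (SS_w/df_w) with p from the F distribution;
    R² = SS_b/SS_total and R²adj = 1 − (1 − R²)(n − 1)/(n − k) for k groups.
    Group order in the output follows descending group code so that with
    beautiful = 1 / ugly = 0 the beautiful group comes first.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if x.shape != g.shape:
        raise ValueError("values and groups must have equal length")
    levels = sorted(set(g.tolist()), reverse=True)
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    n = len(x)
    if n < len(levels) + 1:
        raise ValueError("too few observations for the number of groups")
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    means, sizes, ss_within = [], [], 0.0
    for lev in levels:
        xi = x[g == lev]
        if len(xi) == 0:
            raise ValueError(f"group {lev!r} is empty")
        means.append(float(xi.mean()))
        sizes.append(int(len(xi)))
        ss_within += float(((xi - xi.mean()) ** 2).sum())
    ss_between = ss_total - ss_within
    df_b = len(levels) - 1
    df_w = n - len(levels)
    if ss_within == 0.0:
        raise ValueError("zero within-group variance; F statistic undefined")
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_w
    p = float(sps.f.sf(f_stat, df_b, df_w))
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        r2=float(r2),
        r2_adj=float(r2_adj),
        group_means=tuple(means),
        group_sizes=tuple(sizes),
    )


def pairwise_r2(a, b) -> float:
    """Squared Pearson correlation between two feature vectors (symmetric)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def anova_table(ds: BeautyDataset, scale: str = "both") -> pd.DataFrame:
    """Per-feature one-way ANOVAs against the beauty grouping.

    ``scale`` selects ``"raw"``, ``"z"`` or ``"both"`` feature scales.  F,
    df and p are identical on both scales (the ANOVA is invariant under
    affine rescaling); the group means differ, which is why both are
    carried.  P-values are uncorrected.
    """
    frames = {"raw": ds.features, "z": ds.z_features}
    if scale != "both":
        frames = {scale: frames[scale]}
    rows = []
    for sc, frame in frames.items():
        for name in FEATURE_NAMES:
            res = one_way_anova(frame[name].to_numpy(), ds.labels)
            rows.append(
                {
                    "feature": name,
                    "scale": sc,
                    "F": res.f_stat,
                    "df1": res.df_between,
                    "df2": res.df_within,
                    "p": res.p_value,
                    "R2": res.r2,
                    "R2_adj": res.r2_adj,
                    "mean_beautiful": res.group_means[0],
                    "mean_ugly": res.group_means[1],
                }
            )
    return pd.DataFrame(rows)


def pairwise_r2_table(ds: BeautyDataset) -> pd.DataFrame:
    """Symmetric 8×8 table of squared Pearson correlations between features."""
    cols = list(FEATURE_NAMES)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            r2 = pairwise_r2(ds.features[a], ds.features[b])
            out.loc[a, b] = out.loc[b, a] = r2
    return out


def group_summary(ds: BeautyDataset) -> pd.DataFrame:
    """Per-feature, per-group means and SDs on raw and z scales.

    The z-scale group means satisfy n₁·m₁ + n₂·m₂ = 0 by the pooled
    zero-mean constraint, so a positive beautiful-group z-mean forces a
    negative ugly-group z-mean of magnitude n₁/n₂ times larger or smaller.
    """
    rows = []
    masks = {"beautiful": ds.labels == 1, "ugly": ds.labels == 0}
    for name in FEATURE_NAMES:
        row: dict[str, float | str] = {"feature": name}
        for gname, mask in masks.items():
            row[f"mean_{gname}"] = float(ds.features.loc[mask, name].mean())
            row[f"sd_{gname}"] = float(ds.features.loc[mask, name].std(ddof=1))
            row[f"zmean_{gname}"] = float(ds.z_features.loc[mask, name].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
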