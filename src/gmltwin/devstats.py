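"""Group-level statistics over deviation profiles.

Abnormality maps (percentage of subjects per group with |z| > 1.96 per ROI),
nonparametric group tests (Kruskal-Wallis across groups, Mann-Whitney per
pair), top-10 discriminative ROI ranking with effect direction, and column
similarity (Jaccard overlap of top-10 sets across comparisons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import GmltwinError
from .manifold import Z_THRESHOLD


class EmptyGroupError(GmltwinError):
    pass


@dataclass
class GroupComparison:
    """Pairwise ROI screen between two groups of deviation profiles."""

    group_a: str
    group_b: str
    table: pd.DataFrame  # per ROI: statistic U, p_value, effect (rank-biserial), direction
    top_rois: list[str]  # <= 10 ROI names ranked by evidence


def abnormality_map(z: pd.DataFrame, groups, group: str,
                    threshold: float = Z_THRESHOLD) -> pd.Series:
    """Percentage of subjects in ``group`` with |z| > threshold, per ROI."""
    mask = np.asarray(groups) == group
    if mask.sum() == 0:
        raise EmptyGroupError(f"no subjects in group {group!r}")
    flags = np.abs(z.to_numpy()[mask]) > threshold
    return pd.Series(100.0 * flags.mean(axis=0), index=z.columns, name=group)


def kruskal_wallis(*samples) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p.

    Degenerate contract: if all values across all groups are identical the
    test carries no information — returns (0.0, 1.0).
    """
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise EmptyGroupError("need >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(s, float) for s in samples])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (exact for small untied samples, else
    normal approximation with tie correction)."""
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if len(a) == 0 or len(b) == 0:
        raise EmptyGroupError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def rank_biserial(sample_a, sample_b) -> float:
    """Rank-biserial effect size r = 2U/(n_a n_b) - 1 in [-1, 1]."""
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    u, _ = mann_whitney(a, b)
    return 2.0 * u / (len(a) * len(b)) - 1.0


def rank_top_rois(z: pd.DataFrame, groups, group_a: str, group_b: str,
                  n_top: int = 10) -> GroupComparison:
    """Rank ROIs separating two groups of z-profiles.

    ROIs are ordered by ascending Mann-Whitney p, ties broken by descending
    |rank-biserial| then by column order; direction is the sign of
    median(z_b) - median(z_a): positive = volume increase, negative = atrophy.
    """
    groups = np.asarray(groups)
    za = z.to_numpy()[groups == group_a]
    zb = z.to_numpy()[groups == group_b]
    if za.shape[0] == 0 or zb.shape[0] == 0:
        raise EmptyGroupError(f"empty group among {group_a!r}, {group_b!r}")
    rows = []
    for j, roi in enumerate(z.columns):
        u, p = mann_whitney(za[:, j], zb[:, j])
        eff = 2.0 * u / (za.shape[0] * zb.shape[0]) - 1.0
        dmed = float(np.median(zb[:, j]) - np.median(za[:, j]))
        rows.append((roi, u, p, eff, "increase" if dmed > 0 else "atrophy", dmed))
    table = pd.DataFrame(rows, columns=["roi", "U", "p_value", "effect", "direction",
                                        "median_diff"])
    table["abs_effect"] = table["effect"].abs()
    table = (
        table.reset_index(names="col_order")
        .sort_values(["p_value", "abs_effect", "col_order"],
                     ascending=[True, False, True], kind="stable")
        .drop(columns=["abs_effect", "col_order"])
        .reset_index(drop=True)
    )
    top = table["roi"].head(min(n_top, len(table))).tolist()
    return GroupComparison(group_a, group_b, table, top)


def column_similarity(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Jaccard overlap of top-ROI sets for every pair of group comparisons."""
    if len(comparisons) < 2:
        raise EmptyGroupError("need >= 2 comparisons")
    labels = [f"{c.group_a} vs {c.group_b}" for c in comparisons]
    sets = [set(c.top_rois) for c in comparisons]
    m = np.eye(len(sets))
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            union = sets[i] | sets[j]
            m[i, j] = m[j, i] = len(sets[i] & sets[j]) / len(union) if union else 1.0
    return pd.DataFrame(m, index=labels, columns=labels)
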