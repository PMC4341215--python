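"""Group-comparison statistics for BP estimates across tissue types.

One-way ANOVA with tissue group as the between-subjects factor, preceded
by Levene's homogeneity-of-variance test (mean-centred) and per-group
Shapiro–Wilk normality checks.  Post-hoc pairwise comparisons follow the
variance-homogeneity branch: Bonferroni-corrected pooled-variance t tests
when variances are homogeneous (Levene P > alpha), otherwise Tamhane T2,
implemented as Welch t tests with a Šidák-type correction
``1 - (1 - p)^m`` — a standard approximation to the T2 critical values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupData", "GroupComparisonResult", "compare_groups"]


@dataclass
class GroupData:
    group_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class GroupComparisonResult:
    anova_F: float
    anova_P: float
    levene_P: float
    shapiro_P: dict[str, float]
    posthoc: dict[tuple[str, str], float]
    posthoc_method: str

    def to_dict(self) -> dict:
        return {
            "anova_F": self.anova_F,
            "anova_P": self.anova_P,
            "levene_P": self.levene_P,
            "shapiro_P": dict(self.shapiro_P),
            "posthoc_method": self.posthoc_method,
            "posthoc": {f"{a} vs {b}": p for (a, b), p in self.posthoc.items()},
        }


def _pooled_t_p(x: np.ndarray, y: np.ndarray) -> float:
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.pvalue)


def _welch_t_p(x: np.ndarray, y: np.ndarray) -> float:
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.pvalue)


def compare_groups(
    groups: list[GroupData], alpha: float = 0.05
) -> GroupComparisonResult:
    """One-way ANOVA across groups with assumption checks and post-hocs.

    The post-hoc method is Tamhane T2 when Levene's test rejects variance
    homogeneity at ``alpha`` and Bonferroni otherwise; all pairwise P
    values are capped at 1.  Groups with fewer than 2 values (or a single
    repeated value with n < 2) are rejected as degenerate.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g.values) < 2:
            raise ValueError(f"group {g.group_label!r} has fewer than 2 values")
    samples = [g.values for g in groups]
    labels = [g.group_label for g in groups]

    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        # all observations identical: no between- or within-group variance
        anova_F, anova_P = 0.0, 1.0
        levene_P = 1.0
    else:
        anova_F, anova_P = map(float, sps.f_oneway(*samples))
        if math.isnan(anova_F):  # zero within-group variance throughout
            anova_F, anova_P = 0.0, 1.0
        levene_P = float(sps.levene(*samples, center="mean").pvalue)

    shapiro_P: dict[str, float] = {}
    for label, s in zip(labels, samples):
        if len(s) >= 3 and np.ptp(s) > 0:
            shapiro_P[label] = float(sps.shapiro(s).pvalue)
        else:
            shapiro_P[label] = math.nan

    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    posthoc: dict[tuple[str, str], float] = {}
    if levene_P < alpha:
        method = "Tamhane"
        for i, j in pairs:
            p = _welch_t_p(samples[i], samples[j])
            posthoc[(labels[i], labels[j])] = min(1.0, 1.0 - (1.0 - p) ** m)
    else:
        method = "Bonferroni"
        for i, j in pairs:
            if np.array_equal(samples[i], samples[j]):
                p = 1.0
            else:
                p = _pooled_t_p(samples[i], samples[j])
            posthoc[(labels[i], labels[j])] = min(1.0, p * m)

    return GroupComparisonResult(
        anova_F=anova_F,
        anova_P=anova_P,
        levene_P=levene_P,
        shapiro_P=shapiro_P,
        posthoc=posthoc,
        posthoc_method=method,
    )
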