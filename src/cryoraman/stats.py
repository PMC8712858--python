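"""Group-comparison layer for metric tables.

Two-sample comparisons use the two-tailed Student's t-test. Families of
three or more groups are first screened for normality (Shapiro-Wilk,
alpha = 0.05, per group); any failure routes the whole family to
Kruskal-Wallis with pairwise rank-sum follow-up, otherwise one-way
ANOVA with pairwise t-tests. Either way the pairwise p-values get the
Bonferroni adjustment min(1, m p) with m the number of pairs, and
significance is called at alpha = 0.05 on the adjusted value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    groups: tuple[str, str]
    test_name: str  # "t" | "anova_bonferroni" | "kruskal_wallis"
    statistic: float
    p_value: float
    adjusted_p: float
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 or not 0.0 <= self.adjusted_p <= 1.0:
            raise ValueError("p-values must be in [0, 1]")
        if self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted_p must be >= p_value")
        if self.significant != (self.adjusted_p < ALPHA):
            raise ValueError("significant must equal adjusted_p < alpha")


@dataclass(frozen=True)
class MultiComparisonResult:
    path: str  # "anova_bonferroni" | "kruskal_wallis"
    omnibus_statistic: float
    omnibus_p: float
    pairwise: tuple[ComparisonResult, ...]

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.pairwise)


def _check_sample(x: np.ndarray, name: str, min_n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < min_n:
        raise ValueError(f"sample {name!r} needs at least {min_n} observations")
    if x.var(ddof=1) <= 0:
        raise ValueError(f"sample {name!r} has degenerate (zero) variance")
    return x


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value, min(1, m p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def compare_two(
    a: Sequence[float], b: Sequence[float], labels: tuple[str, str] = ("a", "b")
) -> ComparisonResult:
    """Two-tailed Student's t-test (equal variances); no multiplicity
    adjustment, so adjusted_p = p_value."""
    a = _check_sample(np.asarray(a), labels[0], 2)
    b = _check_sample(np.asarray(b), labels[1], 2)
    stat, p = sps.ttest_ind(a, b, equal_var=True)
    p = float(p)
    return ComparisonResult(labels, "t", float(stat), p, p, p < ALPHA)


def compare_many(
    samples: Mapping[str, Sequence[float]],
    force_nonparametric: bool = False,
    normality_alpha: float = 0.05,
) -> MultiComparisonResult:
    """Multi-group comparison with normality-based test selection.

    Shapiro-Wilk at ``normality_alpha`` per group chooses the path: all
    normal -> one-way ANOVA with pairwise t-tests; any non-normal (or
    ``force_nonparametric``) -> Kruskal-Wallis with pairwise two-sided
    rank-sum tests. Pairwise p-values are Bonferroni-adjusted with
    m = number of pairs.
    """
    if len(samples) < 3:
        raise ValueError("compare_many needs >= 3 groups; use compare_two for 2")
    arrays = {k: _check_sample(np.asarray(v), k, 3) for k, v in samples.items()}

    nonparametric = force_nonparametric or any(
        sps.shapiro(x).pvalue < normality_alpha for x in arrays.values()
    )
    pairs = list(combinations(arrays.keys(), 2))
    m = len(pairs)

    if nonparametric:
        path = "kruskal_wallis"
        stat, p_omni = sps.kruskal(*arrays.values())
        pairwise_test = lambda x, y: sps.mannwhitneyu(x, y, alternative="two-sided")
    else:
        path = "anova_bonferroni"
        stat, p_omni = sps.f_oneway(*arrays.values())
        pairwise_test = lambda x, y: sps.ttest_ind(x, y, equal_var=True)

    results = []
    for ka, kb in pairs:
        s, p = pairwise_test(arrays[ka], arrays[kb])
        adj = bonferroni(float(p), m)
        results.append(
            ComparisonResult((ka, kb), path, float(s), float(p), adj, adj < ALPHA)
        )
    return MultiComparisonResult(path, float(stat), float(p_omni), tuple(results))


def comparisons_to_frame(results: Sequence[ComparisonResult]):
    """Tidy DataFrame of comparison rows (one per pair)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "group_a": r.groups[0],
                "group_b": r.groups[1],
                "test": r.test_name,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "significant": r.significant,
            }
            for r in results
        ]
    )
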