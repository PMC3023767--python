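"""Condition-level statistics: geometric-MFI normalization, SEM, tests.

Two-condition comparisons use the classical unpaired (pooled-variance)
Student t-test; three or more conditions use one-way ANOVA followed by a
Bonferroni post-test in which pairwise t statistics share the pooled
within-group mean square and adjusted p values are ``min(1, m·p)`` for
``m`` comparisons.  Flow-cytometry surface-expression readouts are
summarized as the normalized geometric MFI: the mean geometric mean
fluorescence intensity of the receptor-expressing line divided by that
of the receptor-negative control line.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "geometric_mean",
    "normalized_geometric_mfi",
    "relative_to_reference",
    "sem",
    "unpaired_t_test",
    "anova_bonferroni",
]


@dataclass
class ComparisonResult:
    group_labels: tuple[str, ...]
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value outside [0, 1]")


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(log values)); all values must be positive."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if np.any(v <= 0):
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(v))))


def normalized_geometric_mfi(
    test_geo_mfis: Sequence[float], control_geo_mfis: Sequence[float]
) -> float:
    """Mean test-line geometric MFI over mean control-line geometric MFI."""
    t = np.asarray(test_geo_mfis, dtype=float)
    c = np.asarray(control_geo_mfis, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both replicate sets must be non-empty")
    c_mean = float(c.mean())
    if c_mean == 0:
        raise ValueError("control mean is zero")
    return float(t.mean() / c_mean)


def relative_to_reference(
    values: dict[str, Sequence[float]], reference: str
) -> dict[str, np.ndarray]:
    """Divide every condition's values by the reference-condition mean.

    The reference condition's mean after normalization is exactly 1.
    """
    if reference not in values:
        raise ValueError(f"reference condition {reference!r} missing")
    ref_mean = float(np.mean(values[reference]))
    if ref_mean == 0:
        raise ValueError("reference mean is zero")
    return {k: np.asarray(v, dtype=float) / ref_mean for k, v in values.items()}


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean, sample SD (n−1) over √n; NaN for n < 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def unpaired_t_test(
    group1: Sequence[float],
    group2: Sequence[float],
    labels: tuple[str, str] = ("group1", "group2"),
    welch: bool = False,
) -> ComparisonResult:
    """Two-sided unpaired t-test (pooled variance by default).

    With zero pooled variance, equal means give p = 1 and unequal means
    give p = 0 (perfect separation).
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return ComparisonResult(labels, 0.0, 1.0, method="student_t")
        return ComparisonResult(labels, float("inf"), 0.0, method="student_t")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return ComparisonResult(
        labels,
        float(res.statistic),
        float(res.pvalue),
        method="welch_t" if welch else "student_t",
    )


def anova_bonferroni(
    groups: dict[str, Sequence[float]]
) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """One-way ANOVA plus all-pairs Bonferroni post-test.

    Pairwise t statistics use the pooled within-group mean square (the
    ANOVA error term) with N − k degrees of freedom; adjusted p values
    are ``min(1, m·p)`` over the ``m`` pairwise comparisons.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups (use unpaired_t_test for 2)")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    labels = list(arrays)
    data = [arrays[k] for k in labels]
    n_total = sum(v.size for v in data)
    k = len(data)
    df_within = n_total - k
    ms_within = sum(((v - v.mean()) ** 2).sum() for v in data) / df_within

    if ms_within == 0 and all(np.isclose(v.mean(), data[0].mean()) for v in data):
        omnibus = ComparisonResult(tuple(labels), 0.0, 1.0, method="anova")
    else:
        f_stat, f_p = sps.f_oneway(*data)
        omnibus = ComparisonResult(tuple(labels), float(f_stat), float(f_p), method="anova")

    pairs = list(combinations(labels, 2))
    m = len(pairs)
    results: list[ComparisonResult] = []
    for la, lb in pairs:
        a, b = arrays[la], arrays[lb]
        se = np.sqrt(ms_within * (1.0 / a.size + 1.0 / b.size))
        if se == 0:
            t_stat = 0.0 if a.mean() == b.mean() else float("inf")
            p_raw = 1.0 if a.mean() == b.mean() else 0.0
        else:
            t_stat = float((a.mean() - b.mean()) / se)
            p_raw = float(2.0 * sps.t.sf(abs(t_stat), df_within))
        results.append(
            ComparisonResult(
                (la, lb),
                t_stat,
                p_raw,
                p_adjusted=min(1.0, m * p_raw),
                method="bonferroni_posttest",
            )
        )
    return omnibus, results
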