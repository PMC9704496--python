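"""Normality-routed two-group testing with Bonferroni correction.

The routing rule: Shapiro-Wilk is run on each group at ``alpha_normality``
(default 0.05); if both groups look normal the groups are compared with
Student's two-sample t-test (equal variances; Welch available via a flag),
otherwise with the Wilcoxon rank-sum test. All p-values are two-sided.
Bonferroni adjustment multiplies each raw p by the number of simultaneous
comparisons in the call (e.g. the number of genes in a per-gene usage
comparison), capped at 1.

Any per-sample metric from the other modules can be compared across the two
levels of a metadata feature via :func:`compare_metric_by_feature`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from . import basic, clonality, diversity
from .containers import CohortDataset, RepertoireTable
from .errors import ValidationError
from .usage import cohort_usage_table


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    groups: tuple[str, str]
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    test_used: str  # "t_test", "wilcoxon_rank_sum", or "degenerate"
    p_raw: float
    p_adjusted: float
    m_comparisons: int


def _is_normal(values: np.ndarray, alpha: float) -> bool:
    if np.ptp(values) == 0.0:
        return False  # Shapiro-Wilk undefined for constant data
    return sps.shapiro(values).pvalue > alpha


def route_and_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha_normality: float = 0.05,
    *,
    welch: bool = False,
    metric: str = "",
    groups: tuple[str, str] = ("A", "B"),
    m_comparisons: int = 1,
) -> GroupComparison:
    """Normality-routed two-sided two-group test (see module docstring).

    Each group needs >= 3 values so normality is testable. Two identical
    constant groups yield a degenerate sentinel (test_used="degenerate",
    NaN p-values) rather than a fabricated p.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError(
            "each group needs >= 3 values for normality routing; "
            "with fewer, pick a test directly"
        )

    const_a = np.ptp(a) == 0.0
    const_b = np.ptp(b) == 0.0
    if const_a and const_b and a[0] == b[0]:
        test_used, p_raw = "degenerate", float("nan")
    elif _is_normal(a, alpha_normality) and _is_normal(b, alpha_normality):
        test_used = "t_test"
        p_raw = float(sps.ttest_ind(a, b, equal_var=not welch).pvalue)
    else:
        test_used = "wilcoxon_rank_sum"
        p_raw = float(sps.ranksums(a, b).pvalue)

    p_adj = min(1.0, p_raw * m_comparisons) if np.isfinite(p_raw) else float("nan")
    return GroupComparison(
        metric=metric, groups=groups, n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        test_used=test_used, p_raw=p_raw, p_adjusted=p_adj,
        m_comparisons=m_comparisons,
    )


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """min(1, p·m) for each p, with m = number of p-values supplied."""
    ps = [float(p) for p in p_values]
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p-value {p} outside [0, 1]")
    m = len(ps)
    return [min(1.0, p * m) for p in ps]


# -- per-sample metric registry ---------------------------------------------

def _chao1_estimate(t: RepertoireTable) -> float:
    return diversity.chao1(t)[0]


SAMPLE_METRICS: dict[str, callable] = {
    "read_count": lambda t: float(t.total_reads),
    "clonotype_count": lambda t: float(t.n),
    "mean_freq": lambda t: basic.basic_summary(t).mean_freq,
    "geo_mean_freq": lambda t: basic.basic_summary(t).geo_mean_freq,
    "mean_cdr3nt_len": basic.mean_cdr3nt_length,
    "convergence": basic.convergence,
    "pielou_clonality": clonality.pielou_clonality,
    "clonal_proportion": lambda t, percent=10.0: float(
        clonality.clonal_proportion(t, percent)),
    "shannon_wiener": diversity.shannon_wiener,
    "normalized_shannon_wiener": diversity.normalized_shannon_wiener,
    "inv_simpson": lambda t: diversity.simpson_family(t)[0],
    "gini_simpson": lambda t: diversity.simpson_family(t)[1],
    "d50": diversity.d50,
    "chao1": _chao1_estimate,
    "gini_coefficient": diversity.gini_coefficient,
}

_USAGE_METRICS = {"v_usage": "V", "d_usage": "D", "j_usage": "J"}


def _two_levels(cohort: CohortDataset, feature: str) -> tuple:
    values = cohort.feature_values(feature)
    levels = sorted(values.dropna().unique())
    if len(levels) != 2:
        raise ValidationError(
            f"feature {feature!r} has {len(levels)} levels; exactly 2 required"
        )
    return values, (str(levels[0]), str(levels[1]))


def compare_metric_by_feature(
    cohort: CohortDataset,
    metric: str,
    feature: str,
    alpha_normality: float = 0.05,
    *,
    welch: bool = False,
    weighted: bool = True,
    collapse_alleles: bool = False,
    **metric_kwargs,
) -> list[GroupComparison]:
    """Compare a per-sample metric between the two levels of a feature.

    Scalar metrics yield one comparison (m = 1). The usage metrics
    ``v_usage``/``d_usage``/``j_usage`` yield one comparison per segment
    label, Bonferroni-corrected over the number of labels.
    """
    values, levels = _two_levels(cohort, feature)
    in_a = values.astype(str) == levels[0]
    in_b = values.astype(str) == levels[1]
    samples_a = values.index[in_a]
    samples_b = values.index[in_b]

    if metric in _USAGE_METRICS:
        usage_df = cohort_usage_table(
            cohort, _USAGE_METRICS[metric], weighted, collapse_alleles
        )
        genes = list(usage_df.columns)
        m = len(genes)
        return [
            route_and_test(
                usage_df.loc[samples_a, g], usage_df.loc[samples_b, g],
                alpha_normality, welch=welch,
                metric=f"{metric}:{g}", groups=levels, m_comparisons=m,
            )
            for g in genes
        ]

    if metric not in SAMPLE_METRICS:
        known = sorted(SAMPLE_METRICS) + sorted(_USAGE_METRICS)
        raise ValidationError(f"unknown metric {metric!r}; known: {known}")
    fn = SAMPLE_METRICS[metric]
    per_sample = {t.sample: fn(t, **metric_kwargs) if metric_kwargs
                  else fn(t) for t in cohort}
    return [route_and_test(
        [per_sample[s] for s in samples_a],
        [per_sample[s] for s in samples_b],
        alpha_normality, welch=welch,
        metric=metric, groups=levels, m_comparisons=1,
    )]


def comparisons_frame(results: Sequence[GroupComparison]):
    """Tabulate GroupComparison records (one row each) for TSV export."""
    import pandas as pd
    rows = []
    for r in results:
        row = r.__dict__.copy()
        row["group_a"], row["group_b"] = row.pop("groups")
        rows.append(row)
    return pd.DataFrame(rows)
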