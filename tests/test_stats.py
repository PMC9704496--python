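"""Normality-routed two-group testing and Bonferroni correction."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from repstat import (RepertoireTable, SynthSpec, ValidationError, bonferroni,
                     compare_metric_by_feature, generate_cohort, merge_cohort,
                     route_and_test)


def test_identical_heavy_tailed_groups_give_p_one():
    values = [math.exp(x) for x in range(10)]  # strongly non-normal
    r = route_and_test(values, values)
    assert r.test_used == "wilcoxon_rank_sum"
    assert r.p_raw == pytest.approx(1.0, abs=1e-9)


def test_routing_matches_reference_shapiro_calls():
    rng = np.random.default_rng(42)
    for i in range(20):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20) if i % 2 else rng.lognormal(0, 2, 20)
        r = route_and_test(a, b)
        both_normal = (sps.shapiro(a).pvalue > 0.05
                       and sps.shapiro(b).pvalue > 0.05)
        assert r.test_used == ("t_test" if both_normal else "wilcoxon_rank_sum")
        if both_normal:
            assert r.p_raw == pytest.approx(
                sps.ttest_ind(a, b, equal_var=True).pvalue)
        else:
            assert r.p_raw == pytest.approx(sps.ranksums(a, b).pvalue)


def test_heavy_tailed_group_routes_to_rank_sum():
    rng = np.random.default_rng(7)
    a = rng.normal(0, 1, 20)
    b = rng.lognormal(0, 3, 20)  # heavy-tailed, fails Shapiro-Wilk
    assert route_and_test(a, b).test_used == "wilcoxon_rank_sum"


def test_routing_is_deterministic():
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
    first = route_and_test(a, b)
    again = route_and_test(a, b)
    assert first == again


def test_small_groups_rejected_and_degenerate_sentinel():
    with pytest.raises(ValidationError, match=">= 3"):
        route_and_test([1.0, 2.0], [1.0, 2.0, 3.0])
    r = route_and_test([5.0] * 4, [5.0] * 4)
    assert r.test_used == "degenerate"
    assert math.isnan(r.p_raw) and math.isnan(r.p_adjusted)


def test_constant_group_routes_nonparametric():
    r = route_and_test([5.0] * 4, [1.0, 2.0, 3.0, 4.0])
    assert r.test_used == "wilcoxon_rank_sum"


def test_bonferroni_arithmetic_and_validation():
    assert bonferroni([0.01, 0.04]) == [0.02, 0.08]
    assert bonferroni([0.9, 0.7]) == [1.0, 1.0]
    assert bonferroni([0.3]) == [0.3]
    with pytest.raises(ValidationError):
        bonferroni([0.5, 1.5])


def test_welch_flag_changes_test():
    rng = np.random.default_rng(11)
    a = rng.normal(0, 1, 10)
    b = rng.normal(0, 9, 30)
    student = route_and_test(a, b)
    welch = route_and_test(a, b, welch=True)
    if student.test_used == "t_test":
        assert student.p_raw != welch.p_raw


def _copied_group_cohort():
    """Group B tables are exact copies of group A tables."""
    tables, labels = [], {}
    for i, counts in enumerate([[6, 3, 1], [5, 4, 1], [8, 1, 1], [4, 3, 3]]):
        for grp in ("A", "B"):
            name = f"{grp}{i}"
            tables.append(RepertoireTable.from_counts(name, counts))
            labels[name] = grp
    import pandas as pd
    meta = pd.DataFrame({"grp": pd.Series(labels)})
    meta.index.name = "sample"
    return merge_cohort(tables, meta)


def test_copied_groups_have_equal_means():
    cohort = _copied_group_cohort()
    (r,) = compare_metric_by_feature(cohort, "read_count", "grp")
    assert r.mean_a == r.mean_b
    assert r.m_comparisons == 1


def test_doubled_read_depth_gives_exact_mean_ratio():
    spec = SynthSpec(n_clonotypes=50, total_reads=1000, n_samples=8,
                     group_labels=["A"] * 4 + ["B"] * 4,
                     group_total_reads={"A": 1000, "B": 2000}, seed=5)
    cohort = generate_cohort(spec)
    (r,) = compare_metric_by_feature(cohort, "read_count", "group")
    assert r.mean_b / r.mean_a == 2.0


def test_usage_comparison_bonferroni_bookkeeping():
    spec = SynthSpec(n_clonotypes=60, total_reads=600, n_samples=8,
                     group_labels=["A"] * 4 + ["B"] * 4, seed=9)
    cohort = generate_cohort(spec)
    results = compare_metric_by_feature(cohort, "v_usage", "group")
    genes = {r.metric for r in results}
    assert len(results) == len(genes)
    for r in results:
        assert r.m_comparisons == len(results)
        if not math.isnan(r.p_raw):
            assert r.p_adjusted == min(1.0, r.p_raw * len(results))
            assert r.p_adjusted >= r.p_raw


def test_feature_must_have_two_levels():
    cohort = generate_cohort(SynthSpec(
        n_clonotypes=20, total_reads=200, n_samples=6,
        group_labels=["A"] * 6, seed=1))
    with pytest.raises(ValidationError, match="levels"):
        compare_metric_by_feature(cohort, "read_count", "group")


def test_unknown_metric_is_rejected():
    cohort = generate_cohort(SynthSpec(
        n_clonotypes=20, total_reads=200, n_samples=6,
        group_labels=["A"] * 3 + ["B"] * 3, seed=1))
    with pytest.raises(ValidationError, match="unknown metric"):
        compare_metric_by_feature(cohort, "nope", "group")


def test_null_rejection_rate_calibrated():
    """Routed pipeline holds its nominal size under a Gaussian null."""
    rng = np.random.default_rng(2026)
    rejections = 0
    n_reps = 400
    for _ in range(n_reps):
        r = route_and_test(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
        rejections += r.p_raw < 0.05
    assert 0.02 <= rejections / n_reps <= 0.08
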