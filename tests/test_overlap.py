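"""Overlap: set/frequency metrics, JSD, join contract, naive-scan oracle."""

import math

import numpy as np
import pytest

from repstat import (RepertoireTable, ValidationError, compute_overlap,
                     jsd_v_usage, merge_cohort, overlap_join, pairwise_matrix,
                     set_metrics, frequency_metrics)
from repstat.overlap import (METRIC_NAMES, all_pairs_table, lookup_count,
                             reset_lookup_count, validate_key)

from conftest import POOL, random_table, record_dicts
from _oracles import o_jsd_v_usage, o_overlap_metrics

KEY = ("cdr3nt", "v", "j")


def _pair(rng):
    return random_table(rng, "A"), random_table(rng, "B")


def test_join_identical_and_disjoint():
    a = RepertoireTable.from_counts("A", [4, 2, 2])
    join = overlap_join(a, a)
    assert (join.d_ij, join.only_x, join.only_y) == (3, 0, 0)

    b = RepertoireTable.from_counts("B", [4, 2, 2],
                                    cdr3nt=["TGTAGC", "TGCAGC", "TGTTCA"],
                                    cdr3aa=["CS", "CS", "CS"])
    assert overlap_join(a, b).d_ij == 0


def test_join_conserves_totals_after_duplicate_collapse():
    a = RepertoireTable.from_records("A", [
        {"count": 3, "cdr3nt": "TGTAGC", "cdr3aa": "CS", "v": "V1", "j": "J1"},
        {"count": 5, "cdr3nt": "TGTAGC", "cdr3aa": "CS", "v": "V1", "j": "J1"},
    ])
    join = overlap_join(a, a)
    assert join.X == 8 and join.d_i == 1


def test_set_metrics_hand_set_arithmetic():
    # A = {a,b,c}, B = {b,c,d} on the cdr3nt key
    nts = ["TGTGCAAGC", "TGTAGC", "TGCAGC", "TGTTCAAGC"]
    a = RepertoireTable.from_counts("A", [1, 1, 1], cdr3nt=nts[:3],
                                    cdr3aa=["CAS", "CS", "CS"])
    b = RepertoireTable.from_counts("B", [1, 1, 1], cdr3nt=nts[1:],
                                    cdr3aa=["CS", "CS", "CSS"])
    sm = set_metrics(overlap_join(a, b))
    assert sm.jaccard == 0.5
    assert sm.overlap_coeff == 2 / 3
    assert sm.tversky == 2 / 3          # alpha = beta = 0.5 (Sorensen-Dice)
    assert sm.rel_overlap_div == 2 / 9

    same = set_metrics(overlap_join(a, a))
    assert same.jaccard == 1.0 and same.tversky == 1.0
    assert same.rel_overlap_div == pytest.approx(1 / 3)


def test_morisita_horn_worked_arithmetic():
    a = RepertoireTable.from_counts("A", [6, 3, 1])
    b = RepertoireTable.from_counts("B", [1, 3, 6])
    fm = frequency_metrics(overlap_join(a, b))
    assert fm.morisita_horn == pytest.approx(42 / 92, rel=1e-12)


def test_identity_and_disjoint_frequency_metrics():
    a = RepertoireTable.from_counts("A", [4, 2, 2])  # binary-exact freqs
    fm = frequency_metrics(overlap_join(a, a))
    assert fm.morisita_horn == 1.0
    assert fm.cosine == 1.0
    assert fm.geo_mean_overlap_freq == 1.0
    assert fm.clonewise_geo_sum == 1.0

    b = RepertoireTable.from_counts("B", [4, 2, 2],
                                    cdr3nt=["TGTAGC", "TGCAGC", "TGTTCA"],
                                    cdr3aa=["CS", "CS", "CS"])
    fm0 = frequency_metrics(overlap_join(a, b))
    assert (fm0.morisita_horn, fm0.geo_mean_overlap_freq,
            fm0.clonewise_geo_sum) == (0.0, 0.0, 0.0)
    assert math.isnan(fm0.pearson)


def test_pearson_sentinel_on_degenerate_shared_vectors():
    a = RepertoireTable.from_counts("A", [5, 5])
    fm = frequency_metrics(overlap_join(a, a))  # constant shared freqs
    assert math.isnan(fm.pearson)


def test_jsd_worked_values():
    p = RepertoireTable.from_counts("P", [1, 1], v=["V1", "V2"])
    q = RepertoireTable.from_counts("Q", [2], v=["V1"])
    assert jsd_v_usage(p, q) == pytest.approx(0.31127812445913285, rel=1e-12)
    assert jsd_v_usage(p, p) == 0.0
    r = RepertoireTable.from_counts("R", [1, 1], v=["V8", "V9"])
    assert jsd_v_usage(p, r) == 1.0  # disjoint supports, log2 scale


def test_jsd_requires_resolved_v():
    t = RepertoireTable.from_records("T", [
        {"count": 1, "cdr3nt": "TGTAGC", "cdr3aa": "CS"}])
    ok = RepertoireTable.from_counts("O", [1], v=["V1"])
    with pytest.raises(ValidationError, match="unresolved"):
        jsd_v_usage(t, ok)


def test_key_validation():
    with pytest.raises(ValidationError):
        validate_key(())
    with pytest.raises(ValidationError):
        validate_key(("v", "j"))  # no sequence field
    with pytest.raises(ValidationError):
        validate_key(("cdr3nt", "chain"))
    assert validate_key(["cdr3aa"]) == ("cdr3aa",)


def test_aa_key_coarser_than_nt_key():
    # two nt variants of one aa sequence overlap on the aa key only
    a = RepertoireTable.from_counts("A", [5], cdr3nt=["TGTAGC"], cdr3aa=["CS"])
    b = RepertoireTable.from_counts("B", [5], cdr3nt=["TGCAGC"], cdr3aa=["CS"])
    assert overlap_join(a, b, ("cdr3nt",)).d_ij == 0
    assert overlap_join(a, b, ("cdr3aa",)).d_ij == 1


def test_symmetry_and_bounds_on_random_pairs(rng):
    bounded = ["jaccard", "overlap_coeff", "tversky", "morisita_horn",
               "geo_mean_overlap_freq", "clonewise_geo_sum", "jsd_v_usage"]
    for _ in range(25):
        a, b = _pair(rng)
        ab = compute_overlap(a, b, KEY)
        ba = compute_overlap(b, a, KEY)
        for name in METRIC_NAMES:
            x, y = getattr(ab, name), getattr(ba, name)
            if math.isnan(x):
                assert math.isnan(y)
            else:
                assert x == pytest.approx(y, abs=1e-12)
        for name in bounded:
            v = getattr(ab, name)
            assert -1e-12 <= v <= 1 + 1e-12


def test_oracle_equivalence_naive_quadratic_scan(rng):
    """Every metric matches a literal naive-scan transcription exactly."""
    for _ in range(60):
        a, b = random_table(rng, "A", max_n=6), random_table(rng, "B", max_n=6)
        join = overlap_join(a, b, KEY)
        sm = set_metrics(join)
        fm = frequency_metrics(join)
        want = o_overlap_metrics(record_dicts(a), record_dicts(b), KEY)
        assert sm.jaccard == want["jaccard"]
        assert sm.overlap_coeff == want["overlap_coeff"]
        assert sm.tversky == want["tversky"]
        assert sm.rel_overlap_div == want["rel_overlap_div"]
        assert fm.morisita_horn == want["morisita_horn"]
        assert fm.cosine == want["cosine"]
        assert fm.geo_mean_overlap_freq == want["geo_mean_overlap_freq"]
        assert fm.clonewise_geo_sum == want["clonewise_geo_sum"]
        if math.isnan(want["pearson"]):
            assert math.isnan(fm.pearson)
        else:
            assert fm.pearson == pytest.approx(want["pearson"], rel=1e-12)
        assert jsd_v_usage(a, b) == pytest.approx(
            o_jsd_v_usage(record_dicts(a), record_dicts(b)), rel=1e-12)


def test_join_lookups_grow_linearly():
    """Hash-join contract: lookup count is exactly |a| + |b| + d_i."""
    for n in (10, 40, 160):
        a = RepertoireTable.from_counts("A", [1] * n)
        b = RepertoireTable.from_counts("B", [1] * n)
        reset_lookup_count()
        overlap_join(a, b)
        assert lookup_count() == 3 * n  # n inserts + n inserts + n probes


def test_pairwise_matrix_symmetric_and_complete(rng):
    tables = [random_table(rng, f"S{i}") for i in range(3)]
    cohort = merge_cohort(tables)
    mat = pairwise_matrix(cohort, "jaccard", KEY)
    assert mat.shape == (3, 3)
    assert np.allclose(mat.values, mat.values.T, equal_nan=True)
    assert (np.diag(mat.values) == 1.0).all()

    identical = merge_cohort([
        RepertoireTable.from_counts(s, [4, 2, 2]) for s in ("A", "B", "C")])
    assert (pairwise_matrix(identical, "jaccard").values == 1.0).all()

    long = all_pairs_table(cohort, KEY)
    assert len(long) == 3  # 3 choose 2
    assert set(METRIC_NAMES) <= set(long.columns)


def test_pairwise_matrix_needs_two_samples(rng):
    with pytest.raises(ValidationError):
        pairwise_matrix(merge_cohort([random_table(rng)]), "jaccard")
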