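"""Pairwise repertoire overlap metrics.

Two repertoires are joined on a configurable clonotype key — by default
``(cdr3nt, v, j)``, the strictest common convention; no universal standard
exists, so the key is always explicit in results. The join aggregates each
table into a hash table keyed by the clonotype key (O(|a| + |b|) expected
lookups; a module-level counter exposes the lookup count so the linear
contract is testable), then intersects the key sets.

Set-theoretic metrics use clonotype counts d_i, d_j and the shared count
d_ij; abundance-weighted metrics use the read counts x_i, y_i of shared
clonotypes with whole-sample totals X, Y (Morisita-Horn) or whole-sample
frequencies (cosine, Pearson, F, F2). Σx², Σy² in Morisita-Horn run over the
shared clonotypes, matching the printed symbol definitions; pass
``mh_all_clonotypes=True`` for the variant summing over all clonotypes.
Jensen-Shannon divergence is computed between weighted V-usage vectors on
their union support (0·log 0 = 0), in bits, so it lies in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CohortDataset, RepertoireTable, UNRESOLVED
from .errors import EmptyInputError, ValidationError
from .usage import segment_usage

#: Default clonotype identity for overlap joins.
DEFAULT_KEY: tuple[str, ...] = ("cdr3nt", "v", "j")

_ALLOWED_KEY_FIELDS = ("cdr3nt", "cdr3aa", "v", "d", "j")

#: All pairwise metric names, in output order.
METRIC_NAMES = [
    "morisita_horn", "jaccard", "overlap_coeff", "tversky", "cosine",
    "pearson", "rel_overlap_div", "geo_mean_overlap_freq",
    "clonewise_geo_sum", "jsd_v_usage",
]

# -- lookup instrumentation (used to assert the linear join contract) -------
_lookups = 0


def reset_lookup_count() -> None:
    global _lookups
    _lookups = 0


def lookup_count() -> int:
    return _lookups


def validate_key(key: Sequence[str]) -> tuple[str, ...]:
    key = tuple(key)
    if not key:
        raise ValidationError("clonotype key must be non-empty")
    bad = [f for f in key if f not in _ALLOWED_KEY_FIELDS]
    if bad:
        raise ValidationError(f"unknown key fields {bad}; allowed: {_ALLOWED_KEY_FIELDS}")
    if not ({"cdr3nt", "cdr3aa"} & set(key)):
        raise ValidationError("clonotype key must contain a sequence field")
    return key


@dataclass
class OverlapJoin:
    """Hash-join of two repertoires on a clonotype key."""
    key: tuple[str, ...]
    shared: list[tuple]  # (key, x_count, y_count, x_freq, y_freq), a-order
    d_i: int
    d_j: int
    d_ij: int
    only_x: int
    only_y: int
    X: int
    Y: int


@dataclass(frozen=True)
class SetMetrics:
    jaccard: float
    overlap_coeff: float
    tversky: float
    rel_overlap_div: float


@dataclass(frozen=True)
class FrequencyMetrics:
    morisita_horn: float
    cosine: float
    pearson: float
    geo_mean_overlap_freq: float  # F = sqrt(f_ij * f_ji)
    clonewise_geo_sum: float      # F2 = Σ sqrt(φ_ik φ_jk)


@dataclass(frozen=True)
class OverlapResult:
    sample_a: str
    sample_b: str
    key: tuple[str, ...]
    morisita_horn: float
    jaccard: float
    overlap_coeff: float
    tversky: float
    cosine: float
    pearson: float
    rel_overlap_div: float
    geo_mean_overlap_freq: float
    clonewise_geo_sum: float
    jsd_v_usage: float


def _aggregate(table: RepertoireTable, key: tuple[str, ...]) -> dict:
    """Hash-aggregate (count, freq) by clonotype key, insertion-ordered."""
    global _lookups
    out: dict[tuple, list] = {}
    cols = [table.df[f].tolist() for f in key]
    counts = table.df["count"].tolist()
    freqs = table.df["freq"].tolist()
    for i in range(len(counts)):
        k = tuple(col[i] for col in cols)
        _lookups += 1
        entry = out.get(k)
        if entry is None:
            out[k] = [counts[i], freqs[i]]
        else:
            entry[0] += counts[i]
            entry[1] += freqs[i]
    return out


def overlap_join(
    a: RepertoireTable, b: RepertoireTable,
    key: Sequence[str] = DEFAULT_KEY,
) -> OverlapJoin:
    """Match clonotypes of two samples exactly on the key fields."""
    if a.n == 0 or b.n == 0:
        raise EmptyInputError("overlap requires two non-empty repertoires")
    key = validate_key(key)
    global _lookups
    da = _aggregate(a, key)
    db = _aggregate(b, key)
    shared = []
    for k, (xc, xf) in da.items():
        _lookups += 1
        hit = db.get(k)
        if hit is not None:
            shared.append((k, xc, hit[0], xf, hit[1]))
    d_i, d_j, d_ij = len(da), len(db), len(shared)
    return OverlapJoin(
        key=key, shared=shared, d_i=d_i, d_j=d_j, d_ij=d_ij,
        only_x=d_i - d_ij, only_y=d_j - d_ij,
        X=a.total_reads, Y=b.total_reads,
    )


def set_metrics(join: OverlapJoin, alpha: float = 0.5, beta: float = 0.5) -> SetMetrics:
    """Clonotype-set similarity: Jaccard, overlap coefficient, Tversky
    (α = β = 0.5 is Sørensen-Dice), and relative overlap diversity
    d_ij/(d_i·d_j)."""
    if alpha < 0 or beta < 0:
        raise ValidationError("tversky alpha/beta must be >= 0")
    if join.d_i == 0 or join.d_j == 0:
        raise EmptyInputError("degenerate join: a sample has no clonotypes")
    tversky_den = alpha * join.only_x + beta * join.only_y + join.d_ij
    if tversky_den == 0:
        raise ValidationError(
            "tversky undefined: alpha and beta are both 0 with no shared clonotypes"
        )
    return SetMetrics(
        jaccard=join.d_ij / (join.d_i + join.d_j - join.d_ij),
        overlap_coeff=join.d_ij / min(join.d_i, join.d_j),
        tversky=join.d_ij / tversky_den,
        rel_overlap_div=join.d_ij / (join.d_i * join.d_j),
    )


def frequency_metrics(join: OverlapJoin, mh_all_clonotypes: bool = False,
                      a: Optional[RepertoireTable] = None,
                      b: Optional[RepertoireTable] = None) -> FrequencyMetrics:
    """Abundance-weighted similarity over the shared clonotypes.

    Pearson is NaN when fewer than 2 clonotypes are shared or either shared
    frequency vector is constant. ``mh_all_clonotypes`` switches the
    Morisita-Horn Σx², Σy² terms to whole-sample sums (pass the tables).
    """
    if join.d_ij == 0:
        return FrequencyMetrics(0.0, 0.0, float("nan"), 0.0, 0.0)

    xs = np.array([t[1] for t in join.shared], dtype=float)
    ys = np.array([t[2] for t in join.shared], dtype=float)
    pf = np.array([t[3] for t in join.shared], dtype=float)
    qf = np.array([t[4] for t in join.shared], dtype=float)
    X, Y = join.X, join.Y

    if mh_all_clonotypes:
        if a is None or b is None:
            raise ValidationError("mh_all_clonotypes needs the two tables")
        sx2 = float(np.sum(a.counts.astype(float) ** 2))
        sy2 = float(np.sum(b.counts.astype(float) ** 2))
    else:
        sx2 = float(np.sum(xs * xs))
        sy2 = float(np.sum(ys * ys))
    mh = 2.0 * float(np.sum(xs * ys)) / ((sx2 / (X * X) + sy2 / (Y * Y)) * X * Y)

    cosine = float(np.sum(pf * qf)) / math.sqrt(
        float(np.sum(pf * pf)) * float(np.sum(qf * qf)))

    if join.d_ij < 2:
        pearson = float("nan")
    else:
        dp = pf - float(np.sum(pf)) / join.d_ij
        dq = qf - float(np.sum(qf)) / join.d_ij
        sp = float(np.sum(dp * dp))
        sq = float(np.sum(dq * dq))
        if sp == 0.0 or sq == 0.0:
            pearson = float("nan")
        else:
            pearson = float(np.sum(dp * dq)) / math.sqrt(sp * sq)

    f_ij = float(np.sum(pf))
    f_ji = float(np.sum(qf))
    f2 = float(np.sum(np.sqrt(pf * qf)))
    return FrequencyMetrics(mh, cosine, pearson, math.sqrt(f_ij * f_ji), f2)


def jsd_v_usage(a: RepertoireTable, b: RepertoireTable,
                collapse_alleles: bool = False) -> float:
    """Jensen-Shannon divergence (bits) between weighted V-usage vectors."""
    for t in (a, b):
        if set(t.df["v"]) == {UNRESOLVED}:
            raise ValidationError(
                f"sample {t.sample!r} has only unresolved V segments"
            )
    p_usage = segment_usage(a, "V", weighted=True,
                            collapse_alleles=collapse_alleles).values
    q_usage = segment_usage(b, "V", weighted=True,
                            collapse_alleles=collapse_alleles).values
    support = sorted(set(p_usage) | set(q_usage))
    p = [p_usage.get(g, 0.0) for g in support]
    q = [q_usage.get(g, 0.0) for g in support]

    def kl(vec, mid):
        return sum(v * math.log2(v / m) for v, m in zip(vec, mid) if v > 0)

    mid = [(pi + qi) / 2.0 for pi, qi in zip(p, q)]
    return 0.5 * kl(p, mid) + 0.5 * kl(q, mid)


def compute_overlap(
    a: RepertoireTable, b: RepertoireTable,
    key: Sequence[str] = DEFAULT_KEY,
    alpha: float = 0.5, beta: float = 0.5,
) -> OverlapResult:
    """All ten overlap metrics for one sample pair."""
    join = overlap_join(a, b, key)
    sm = set_metrics(join, alpha, beta)
    fm = frequency_metrics(join)
    return OverlapResult(
        sample_a=a.sample, sample_b=b.sample, key=join.key,
        morisita_horn=fm.morisita_horn, jaccard=sm.jaccard,
        overlap_coeff=sm.overlap_coeff, tversky=sm.tversky,
        cosine=fm.cosine, pearson=fm.pearson,
        rel_overlap_div=sm.rel_overlap_div,
        geo_mean_overlap_freq=fm.geo_mean_overlap_freq,
        clonewise_geo_sum=fm.clonewise_geo_sum,
        jsd_v_usage=jsd_v_usage(a, b),
    )


def pair_metric(a: RepertoireTable, b: RepertoireTable, metric: str,
                key: Sequence[str] = DEFAULT_KEY,
                alpha: float = 0.5, beta: float = 0.5) -> float:
    """One named metric for one pair (dispatch helper)."""
    if metric not in METRIC_NAMES:
        raise ValidationError(f"unknown metric {metric!r}; known: {METRIC_NAMES}")
    if metric == "jsd_v_usage":
        return jsd_v_usage(a, b)
    join = overlap_join(a, b, key)
    if metric in ("jaccard", "overlap_coeff", "tversky", "rel_overlap_div"):
        return getattr(set_metrics(join, alpha, beta), metric)
    return getattr(frequency_metrics(join), metric)


def pairwise_matrix(
    cohort: CohortDataset, metric: str,
    key: Sequence[str] = DEFAULT_KEY,
    alpha: float = 0.5, beta: float = 0.5,
) -> pd.DataFrame:
    """Symmetric sample × sample matrix of one metric.

    Each unordered pair is computed once; the diagonal is metric(self, self).
    """
    if len(cohort) < 2:
        raise ValidationError("pairwise matrix needs at least 2 samples")
    samples = cohort.samples
    mat = pd.DataFrame(np.nan, index=samples, columns=samples, dtype=float)
    for s in samples:
        mat.loc[s, s] = pair_metric(cohort[s], cohort[s], metric, key, alpha, beta)
    for sa, sb in combinations(samples, 2):
        val = pair_metric(cohort[sa], cohort[sb], metric, key, alpha, beta)
        mat.loc[sa, sb] = val
        mat.loc[sb, sa] = val
    return mat


def all_pairs_table(
    cohort: CohortDataset,
    key: Sequence[str] = DEFAULT_KEY,
    alpha: float = 0.5, beta: float = 0.5,
) -> pd.DataFrame:
    """Long-format table: one row per unordered sample pair, all metrics."""
    if len(cohort) < 2:
        raise ValidationError("overlap table needs at least 2 samples")
    rows = []
    for sa, sb in combinations(cohort.samples, 2):
        res = compute_overlap(cohort[sa], cohort[sb], key, alpha, beta)
        row = {"sample_a": sa, "sample_b": sb}
        row.update({f.name: getattr(res, f.name) for f in fields(res)
                    if f.name in METRIC_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
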