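"""V/D/J segment usage vectors and V-J pairing matrices.

Weighted usage of a segment is the summed clonotype frequency of clones
carrying it; unweighted usage is the fraction of distinct clonotypes
carrying it. Both sum to 1 over the segment labels of a sample, with
``unresolved`` kept as its own category (renormalizing it away would
silently distort the vectors).

Allele-level labels (``TRBV05-05*01``) are kept verbatim by default;
``collapse_alleles=True`` truncates at ``*`` for gene-level aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import CohortDataset, RepertoireTable
from .errors import EmptyInputError, ValidationError

_SEGMENT_COLUMNS = {"V": "v", "D": "d", "J": "j"}


@dataclass(frozen=True)
class UsageVector:
    segment_class: str  # "V", "D", or "J"
    weighted: bool
    values: dict[str, float]


@dataclass(frozen=True)
class VJMatrix:
    weighted: bool
    values: dict[tuple[str, str], float]

    def to_frame(self) -> pd.DataFrame:
        """Wide V × J frame, absent combinations filled with 0."""
        if not self.values:
            return pd.DataFrame()
        ser = pd.Series(self.values)
        ser.index = pd.MultiIndex.from_tuples(ser.index, names=["v", "j"])
        return ser.unstack(fill_value=0.0).sort_index().sort_index(axis=1)


def _segment_column(table: RepertoireTable, segment_class: str,
                    collapse_alleles: bool) -> pd.Series:
    seg = segment_class.upper()
    if seg not in _SEGMENT_COLUMNS:
        raise ValidationError(f"segment_class must be V, D, or J, got {segment_class!r}")
    col = table.df[_SEGMENT_COLUMNS[seg]]
    if collapse_alleles:
        col = col.str.split("*").str[0]
    return col


def segment_usage(
    table: RepertoireTable,
    segment_class: str,
    weighted: bool = True,
    collapse_alleles: bool = False,
) -> UsageVector:
    """Per-sample usage distribution of one segment class."""
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")
    labels = _segment_column(table, segment_class, collapse_alleles)
    if weighted:
        grouped = table.df["freq"].groupby(labels.values).sum()
    else:
        grouped = labels.value_counts() / table.n
    return UsageVector(
        segment_class.upper(), weighted,
        {str(k): float(v) for k, v in grouped.sort_index().items()},
    )


def vj_matrix(
    table: RepertoireTable,
    weighted: bool = True,
    collapse_alleles: bool = False,
) -> VJMatrix:
    """Joint V-J usage; cell (v, j) is the aggregate frequency (or clonotype
    fraction) of clonotypes carrying that segment pair."""
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")
    vs = _segment_column(table, "V", collapse_alleles)
    js = _segment_column(table, "J", collapse_alleles)
    if weighted:
        grouped = table.df["freq"].groupby([vs.values, js.values]).sum()
    else:
        grouped = pd.Series(1.0 / table.n, index=range(table.n)).groupby(
            [vs.values, js.values]).sum()
    return VJMatrix(
        weighted,
        {(str(v), str(j)): float(x) for (v, j), x in grouped.sort_index().items()},
    )


def cohort_usage_table(
    cohort: CohortDataset,
    segment_class: str,
    weighted: bool = True,
    collapse_alleles: bool = False,
) -> pd.DataFrame:
    """Sample × segment usage matrix over the union of observed labels.

    Absent segments are filled with 0, so every row still sums to 1.
    """
    if len(cohort) == 0:
        raise EmptyInputError("empty cohort")
    rows = {
        t.sample: segment_usage(t, segment_class, weighted, collapse_alleles).values
        for t in cohort
    }
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    out.index.name = "sample"
    return out[sorted(out.columns)]


def group_mean_usage(
    cohort: CohortDataset,
    segment_class: str,
    feature: str,
    weighted: bool = True,
    collapse_alleles: bool = False,
) -> pd.DataFrame:
    """Group-level usage: unweighted mean of per-sample usage vectors."""
    usage = cohort_usage_table(cohort, segment_class, weighted, collapse_alleles)
    groups = cohort.feature_values(feature)
    return usage.groupby(groups).mean()
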