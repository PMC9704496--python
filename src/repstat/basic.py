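"""Fundamental per-sample repertoire metrics.

Given clonotype frequencies :math:`p_i` (``count/total``, so ``Σp_i = 1``)
over the :math:`n` distinct clonotypes of a sample, this module computes
read and clonotype counts, the arithmetic and geometric mean clonotype
frequency, the frequency-weighted mean CDR3 nucleotide length
:math:`Σ len(nt_i)·p_i`, convergence (the mean number of distinct CDR3
nucleotide sequences encoding one CDR3 amino-acid sequence), and the
nucleotide-length spectratype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CohortDataset, RepertoireTable
from .errors import EmptyInputError, ValidationError


@dataclass(frozen=True)
class BasicMetrics:
    read_count: int
    clonotype_count: int
    mean_freq: float
    geo_mean_freq: float
    mean_cdr3nt_len: float
    convergence: float


@dataclass(frozen=True)
class Spectratype:
    """Aggregate clonotype frequency per CDR3 length (nt or aa)."""
    bins: dict[int, float]
    alphabet: str  # "nt" or "aa"


def _check_nonempty(table: RepertoireTable) -> None:
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")


def basic_summary(table: RepertoireTable) -> BasicMetrics:
    """All six basic metrics; geometric mean is computed in log space."""
    _check_nonempty(table)
    freqs = table.freqs
    if np.any(freqs <= 0):
        raise ValidationError(
            "all clonotype frequencies must be > 0 (geometric mean undefined)"
        )
    geo = float(np.exp(np.mean(np.log(freqs))))
    return BasicMetrics(
        read_count=table.total_reads,
        clonotype_count=table.n,
        mean_freq=float(np.mean(freqs)),
        geo_mean_freq=geo,
        mean_cdr3nt_len=mean_cdr3nt_length(table),
        convergence=convergence(table),
    )


def mean_cdr3nt_length(table: RepertoireTable, weighted: bool = True) -> float:
    """Mean CDR3 nt length, frequency-weighted by default."""
    _check_nonempty(table)
    lengths = table.df["cdr3nt"].str.len().to_numpy(dtype=float)
    if weighted:
        return float(np.sum(lengths * table.freqs))
    return float(np.mean(lengths))


def convergence(table: RepertoireTable) -> float:
    """Mean, over CDR3 amino-acid groups, of distinct encoding nt sequences.

    V/D/J labels are ignored: two nt variants with different V calls but the
    same amino-acid CDR3 still count as convergent encodings.
    """
    _check_nonempty(table)
    return float(table.df.groupby("cdr3aa")["cdr3nt"].nunique().mean())


def spectratype_nt(table: RepertoireTable) -> Spectratype:
    """Clonotype frequency aggregated by CDR3 nucleotide length."""
    _check_nonempty(table)
    grouped = table.df.groupby(table.df["cdr3nt"].str.len())["freq"].sum()
    return Spectratype({int(k): float(v) for k, v in grouped.items()}, "nt")


def basic_table(cohort: CohortDataset) -> pd.DataFrame:
    """One row of basic metrics per sample."""
    if len(cohort) == 0:
        raise EmptyInputError("empty cohort")
    rows = []
    for t in cohort:
        m = basic_summary(t)
        rows.append({"sample": t.sample, **m.__dict__})
    return pd.DataFrame(rows)
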