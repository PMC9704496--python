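"""Diversity and richness indices.

All entropies use the natural log. With frequencies :math:`p_i` over
:math:`n` clonotypes and Simpson's :math:`D = \\sum p_i^2`:

* Shannon–Wiener index: :math:`e^{H}` with :math:`H = -\\sum p_i \\ln p_i`
  (a Hill number of order 1; between 1 and n).
* Normalized Shannon–Wiener: :math:`e^{H} / \\ln n`. Note this is *not*
  Pielou's evenness; the conventional :math:`H/\\ln n` is available via
  ``entropy_normalization=True``.
* Inverse Simpson :math:`1/D` and Gini–Simpson :math:`1-D`.
* D50: the percentage of distinct clonotypes needed to reach half of all
  reads (count-based cumulative, descending).
* Chao1 richness: :math:`S + f_1(f_1-1) / (2(f_2+1))` from singleton and
  doubleton clonotype counts, with the classical variance
  :math:`f_2 (r^2/2 + r^3 + r^4/4)`, :math:`r=f_1/f_2` (NaN when
  :math:`f_2 = 0`).
* Gini coefficient: twice the area between the equality line and the
  Lorenz polyline of sorted frequencies (trapezoid rule, exact for step
  distributions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CohortDataset, RepertoireTable
from .errors import EmptyInputError, ValidationError


@dataclass(frozen=True)
class DiversityProfile:
    shannon_wiener: float
    normalized_shannon_wiener: float
    inv_simpson: float
    gini_simpson: float
    d50: float
    chao1: float
    chao1_var: float
    gini_coeff: float


def _freqs(table: RepertoireTable) -> np.ndarray:
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")
    freqs = table.freqs
    if np.any(freqs <= 0):
        raise ValidationError("all clonotype frequencies must be > 0")
    return freqs


def shannon_wiener(table: RepertoireTable) -> float:
    """exp of the Shannon entropy of the clonotype frequencies."""
    freqs = _freqs(table)
    return float(np.exp(-np.sum(freqs * np.log(freqs))))


def normalized_shannon_wiener(
    table: RepertoireTable, entropy_normalization: bool = False
) -> float:
    """exp(H)/ln n by default; H/ln n (Pielou) when entropy_normalization."""
    freqs = _freqs(table)
    if table.n < 2:
        raise ValidationError(
            "normalized Shannon-Wiener undefined for n < 2 (ln n = 0)"
        )
    h = -float(np.sum(freqs * np.log(freqs)))
    num = h if entropy_normalization else math.exp(h)
    return num / math.log(table.n)


def simpson_family(table: RepertoireTable) -> tuple[float, float]:
    """(inverse Simpson 1/D, Gini-Simpson 1-D) with D = Σ p²."""
    freqs = _freqs(table)
    d = float(np.sum(freqs * freqs))
    return 1.0 / d, 1.0 - d


def d50(table: RepertoireTable) -> float:
    """Percentage of distinct clonotypes holding ≥ 50% of reads."""
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")
    counts = table.counts  # descending count, cdr3nt tie-break
    cum = np.cumsum(counts)
    k = int(np.searchsorted(2 * cum, table.total_reads, side="left")) + 1
    return 100.0 * min(k, table.n) / table.n


def chao1(table: RepertoireTable) -> tuple[float, float]:
    """(Chao1 richness estimate, its variance; variance NaN when f2 = 0)."""
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")
    counts = table.counts
    s = table.n
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    estimate = s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return estimate, float("nan")
    r = f1 / f2
    return estimate, f2 * (0.5 * r**2 + r**3 + 0.25 * r**4)


def gini_coefficient(table: RepertoireTable) -> float:
    """Gini inequality of clonotype frequencies via the Lorenz curve."""
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")
    freqs = np.sort(table.freqs)
    cum = np.concatenate(([0.0], np.cumsum(freqs)))
    # trapezoid areas over n equal-width steps of the Lorenz polyline
    area = float(np.sum((cum[:-1] + cum[1:]) / 2.0)) / table.n
    return (0.5 - area) / 0.5


def diversity_profile(table: RepertoireTable) -> DiversityProfile:
    inv, gini_s = simpson_family(table)
    est, var = chao1(table)
    return DiversityProfile(
        shannon_wiener=shannon_wiener(table),
        normalized_shannon_wiener=normalized_shannon_wiener(table),
        inv_simpson=inv,
        gini_simpson=gini_s,
        d50=d50(table),
        chao1=est,
        chao1_var=var,
        gini_coeff=gini_coefficient(table),
    )


def diversity_table(cohort: CohortDataset) -> pd.DataFrame:
    """One row per sample, one column per diversity index."""
    if len(cohort) == 0:
        raise EmptyInputError("empty cohort")
    rows = []
    for t in cohort:
        p = diversity_profile(t)
        rows.append({"sample": t.sample, **p.__dict__})
    return pd.DataFrame(rows)
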