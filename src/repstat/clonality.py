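"""Evenness and clonal-expansion metrics.

Clonality here is 1 − Pielou's evenness,

.. math:: 1 + \\frac{\\sum_i p_i \\ln p_i}{\\ln n},

which is 0 for a perfectly even repertoire and approaches 1 as reads
concentrate in few clones. The abundance decomposition assigns each
clonotype to one frequency band — by default the five bands used for
stacked relative-abundance plots: rare (0, 1e-5], small (1e-5, 1e-4],
medium (1e-4, 1e-3], large (1e-3, 1e-2], hyperexpanded (1e-2, 1].
Bands are half-open ``(lower, upper]`` so every frequency maps to exactly
one band; a clone at exactly 0.01 is "large", not "hyperexpanded".
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .containers import ClonotypeRecord, RepertoireTable
from .errors import EmptyInputError, ValidationError

#: (label, lower bound exclusive, upper bound inclusive) on clonotype frequency.
DEFAULT_BANDS: list[tuple[str, float, float]] = [
    ("hyperexpanded", 1e-2, 1.0),
    ("large", 1e-3, 1e-2),
    ("medium", 1e-4, 1e-3),
    ("small", 1e-5, 1e-4),
    ("rare", 0.0, 1e-5),
]


def validate_bands(bands: Sequence[tuple[str, float, float]]) -> None:
    """Bands must be non-overlapping, contiguous, and cover (0, 1]."""
    if not bands:
        raise ValidationError("empty band set")
    for label, lo, hi in bands:
        if not (0.0 <= lo < hi <= 1.0):
            raise ValidationError(f"band {label!r}: need 0 <= lower < upper <= 1")
    ordered = sorted(bands, key=lambda b: b[1])
    if ordered[0][1] != 0.0 or ordered[-1][2] != 1.0:
        raise ValidationError("bands must cover (0, 1]")
    for (_, _, hi), (label, lo, _) in zip(ordered, ordered[1:]):
        if abs(hi - lo) > 1e-15:
            raise ValidationError(f"bands not contiguous at {label!r} (gap or overlap)")


def extreme_clonotypes(
    table: RepertoireTable, k: int, which: str = "most"
) -> list[ClonotypeRecord]:
    """The k most or least frequent clonotypes, ties broken by cdr3nt."""
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")
    if which not in ("most", "least"):
        raise ValidationError(f"which must be 'most' or 'least', got {which!r}")
    if not 1 <= k <= table.n:
        raise ValidationError(f"k={k} outside [1, {table.n}]")
    ascending = which == "least"
    ordered = table.df.sort_values(
        ["freq", "cdr3nt"], ascending=[ascending, True], kind="mergesort"
    ).head(k)
    return [
        ClonotypeRecord(int(r.count), float(r.freq), r.cdr3nt, r.cdr3aa,
                        r.v, r.d, r.j, table.sample)
        for r in ordered.itertuples(index=False)
    ]


def pielou_clonality(table: RepertoireTable) -> float:
    """1 − Pielou evenness; 1.0 by convention for a single-clonotype sample."""
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")
    if table.n == 1:
        return 1.0
    freqs = table.freqs
    value = 1.0 + float(np.sum(freqs * np.log(freqs))) / math.log(table.n)
    # float cancellation can leave a tiny negative residue for uniform tables
    return min(1.0, max(0.0, value))


def clonal_proportion(table: RepertoireTable, percent: float) -> int:
    """Smallest number of top clonotypes holding ≥ percent% of all reads."""
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")
    if not 0.0 < percent <= 100.0:
        raise ValidationError(f"percent must be in (0, 100], got {percent}")
    counts = table.counts  # canonical order: descending count
    threshold = percent * table.total_reads / 100.0
    cum = np.cumsum(counts)
    k = int(np.searchsorted(cum, threshold - 1e-9, side="left")) + 1
    return min(k, table.n)


def abundance_decomposition(
    table: RepertoireTable,
    bands: Sequence[tuple[str, float, float]] = DEFAULT_BANDS,
) -> dict[str, float]:
    """Aggregate frequency per abundance band; values sum to 1."""
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")
    validate_bands(bands)
    out = {label: 0.0 for label, _, _ in bands}
    freqs = table.freqs
    for label, lo, hi in bands:
        mask = (freqs > lo) & (freqs <= hi)
        out[label] = float(freqs[mask].sum())
    return out
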