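"""CDR3 amino-acid spectratype and fixed-length k-mer motif counting.

Motifs are counted with a sliding window of width k over each clonotype's
CDR3 (amino-acid or nucleotide), once per occurrence — repeats within one
CDR3 all count. Unweighted counting adds 1 per occurrence; weighted adds
the clonotype's read count. Sequences shorter than k contribute nothing,
so the unweighted total is exactly Σ max(0, len − k + 1) over clonotypes.
The default k = 6 matches the motif length conventional for CDR3 studies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .basic import Spectratype
from .containers import CohortDataset, RepertoireTable
from .errors import EmptyInputError, ValidationError


@dataclass(frozen=True)
class MotifCounts:
    alphabet: str  # "aa" or "nt"
    k: int
    weighted: bool
    counts: dict[str, int]


def aa_spectratype(table: RepertoireTable) -> Spectratype:
    """Clonotype frequency aggregated by CDR3 amino-acid length."""
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")
    grouped = table.df.groupby(table.df["cdr3aa"].str.len())["freq"].sum()
    return Spectratype({int(k): float(v) for k, v in grouped.items()}, "aa")


def kmer_counts(
    table: RepertoireTable,
    alphabet: str = "aa",
    k: int = 6,
    weighted: bool = False,
) -> MotifCounts:
    """Count all k-mers across the sample's CDR3 sequences."""
    if table.n == 0:
        raise EmptyInputError("empty repertoire table")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if alphabet not in ("aa", "nt"):
        raise ValidationError(f"alphabet must be 'aa' or 'nt', got {alphabet!r}")
    col = "cdr3aa" if alphabet == "aa" else "cdr3nt"
    counts: Counter[str] = Counter()
    for seq, c in zip(table.df[col], table.df["count"]):
        w = int(c) if weighted else 1
        for i in range(len(seq) - k + 1):
            counts[seq[i:i + k]] += w
    return MotifCounts(alphabet, k, weighted, dict(counts))


def top_motifs(counts: MotifCounts, m: int) -> list[tuple[str, int]]:
    """Top-m motifs by count; ties resolved lexicographically."""
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    ordered = sorted(counts.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:m]


def cohort_kmer_counts(
    cohort: CohortDataset,
    alphabet: str = "aa",
    k: int = 6,
    weighted: bool = False,
) -> MotifCounts:
    """Group-level motif table: sum of per-sample counts."""
    if len(cohort) == 0:
        raise EmptyInputError("empty cohort")
    total: Counter[str] = Counter()
    for t in cohort:
        total.update(kmer_counts(t, alphabet, k, weighted).counts)
    return MotifCounts(alphabet, k, weighted, dict(total))
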