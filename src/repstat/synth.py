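"""Seeded synthetic repertoire and cohort generation.

The generator emulates the shape of post-processed TCR-beta clonotype
tables: heavy-tailed clonotype abundances, exact ``freq = count/total``,
in-frame CDR3 nucleotide sequences built codon-wise from the 61 sense
codons (so the amino-acid column is always a valid standard-genetic-code
translation — inputs are assumed pre-filtered for non-coding CDR3s), and
V/D/J labels drawn uniformly from fixed TRB allele lists.

Abundance models: ``uniform``; ``geometric`` with ratio r (proportions
r^0, r^1, …); ``power_law`` with exponent s (Zipf, proportions i^-s).
Ideal proportions are largest-remainder-rounded so counts sum exactly to
``total_reads`` (each clonotype keeps at least one read). Identical seeds
give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._genetic_code import SENSE_CODONS, translate
from .containers import CohortDataset, RepertoireTable
from .errors import ValidationError
from .io import merge_cohort

DEFAULT_V_ALLELES = tuple(
    f"TRBV{g:02d}-01*01" for g in (2, 4, 5, 6, 7, 9, 11, 13, 18, 20, 28, 30)
)
DEFAULT_D_ALLELES = ("TRBD01-01*01", "TRBD02-01*01", "unresolved")
DEFAULT_J_ALLELES = tuple(
    f"TRBJ{g}-0{j}*01" for g, js in ((1, range(1, 7)), (2, range(1, 8))) for j in js
)


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one generated repertoire/cohort."""

    n_clonotypes: int = 1000
    total_reads: int = 100_000
    abundance_model: str = "power_law"  # uniform | geometric | power_law
    model_param: float = 1.5            # r for geometric, s for power_law
    cdr3_length_range: tuple[int, int] = (8, 20)  # codons
    v_alleles: Sequence[str] = DEFAULT_V_ALLELES
    d_alleles: Sequence[str] = DEFAULT_D_ALLELES
    j_alleles: Sequence[str] = DEFAULT_J_ALLELES
    n_samples: int = 1
    group_labels: Optional[Sequence[str]] = None
    group_total_reads: Optional[Mapping[str, int]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_clonotypes < 1:
            raise ValidationError("n_clonotypes must be >= 1")
        if self.total_reads < self.n_clonotypes:
            raise ValidationError(
                f"total_reads={self.total_reads} < n_clonotypes={self.n_clonotypes}"
            )
        lo, hi = self.cdr3_length_range
        if not 1 <= lo <= hi:
            raise ValidationError("cdr3_length_range must satisfy 1 <= min <= max")
        if self.abundance_model not in ("uniform", "geometric", "power_law"):
            raise ValidationError(
                f"unknown abundance model {self.abundance_model!r}"
            )
        if self.abundance_model == "geometric" and not 0 < self.model_param <= 1:
            raise ValidationError("geometric ratio must be in (0, 1]")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.group_labels is not None and len(self.group_labels) != self.n_samples:
            raise ValidationError("group_labels length must equal n_samples")


def _abundance_proportions(spec: SynthSpec) -> np.ndarray:
    n = spec.n_clonotypes
    if spec.abundance_model == "uniform":
        raw = np.ones(n)
    elif spec.abundance_model == "geometric":
        raw = spec.model_param ** np.arange(n)
    else:  # power_law (Zipf)
        raw = np.arange(1, n + 1, dtype=float) ** -spec.model_param
    return raw / raw.sum()


def largest_remainder_counts(proportions: np.ndarray, total: int) -> np.ndarray:
    """Round ideal allocations to integers summing exactly to ``total``.

    Every clonotype keeps at least one read (total >= n is required), so
    the result is a valid count vector.
    """
    n = len(proportions)
    if total < n:
        raise ValidationError(f"total={total} < number of clonotypes {n}")
    ideal = proportions * total
    counts = np.floor(ideal).astype(np.int64)
    remainder = int(total - counts.sum())
    if remainder > 0:
        order = np.argsort(-(ideal - counts), kind="stable")
        counts[order[:remainder]] += 1
    # guarantee count >= 1: move reads from the largest bins to empty ones
    while (counts == 0).any():
        zero = int(np.argmin(counts))
        rich = int(np.argmax(counts))
        counts[zero] += 1
        counts[rich] -= 1
    return counts


def _random_cdr3nt(rng: np.random.Generator, n: int,
                   length_range: tuple[int, int]) -> list[str]:
    """n distinct in-frame CDR3 nt sequences of codon length in range."""
    lo, hi = length_range
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        n_codons = int(rng.integers(lo, hi + 1))
        idx = rng.integers(0, len(SENSE_CODONS), n_codons)
        seq = "".join(SENSE_CODONS[i] for i in idx)
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def generate_repertoire(spec: SynthSpec, sample: str = "S1") -> RepertoireTable:
    """One synthetic repertoire; deterministic for a given spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = largest_remainder_counts(_abundance_proportions(spec), spec.total_reads)
    cdr3nt = _random_cdr3nt(rng, spec.n_clonotypes, spec.cdr3_length_range)
    frame = pd.DataFrame({
        "count": counts,
        "cdr3nt": cdr3nt,
        "cdr3aa": [translate(s) for s in cdr3nt],
        "v": rng.choice(list(spec.v_alleles), spec.n_clonotypes),
        "d": rng.choice(list(spec.d_alleles), spec.n_clonotypes),
        "j": rng.choice(list(spec.j_alleles), spec.n_clonotypes),
    })
    return RepertoireTable(sample, frame)


def generate_cohort(spec: SynthSpec) -> CohortDataset:
    """Cohort of ``n_samples`` repertoires with optional 2-level grouping.

    Per-sample seeds are derived deterministically from the master seed;
    ``group_total_reads`` overrides ``total_reads`` per group label, so a
    construction like "group B has doubled read depth" is exact.
    """
    spec.validate()
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_samples)
    tables = []
    meta_rows = {}
    for i in range(spec.n_samples):
        name = f"S{i + 1:02d}"
        label = spec.group_labels[i] if spec.group_labels is not None else None
        total = spec.total_reads
        if label is not None and spec.group_total_reads:
            total = spec.group_total_reads.get(label, total)
        child = replace(
            spec, seed=int(child_seeds[i] & 0x7FFFFFFF),
            total_reads=total, n_samples=1,
            group_labels=None, group_total_reads=None,
        )
        tables.append(generate_repertoire(child, sample=name))
        if label is not None:
            meta_rows[name] = label
    metadata = None
    if meta_rows:
        metadata = pd.DataFrame({"group": pd.Series(meta_rows)})
        metadata.index.name = "sample"
    return merge_cohort(tables, metadata)
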