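"""Canonical in-memory containers for clonotype tables.

A :class:`RepertoireTable` holds one sample's clonotype table as a pandas
DataFrame with the canonical columns ``count, freq, cdr3nt, cdr3aa, v, d, j``.
Construction canonicalizes the table:

* rows with count < 1 are dropped (a repertoire is built from observed reads);
* duplicate clonotypes — identical ``(cdr3nt, v, d, j)`` — are merged by
  summing counts;
* rows are ordered by descending count, then lexicographic ``cdr3nt``
  (a deterministic tie rule used throughout the package);
* frequencies are recomputed as ``count / total`` unless the supplied ``freq``
  column already sums to 1 within 1e-3 (tolerating upstream rounding), in
  which case the upstream values are preserved.

A :class:`CohortDataset` bundles many repertoires with an optional per-sample
metadata table (categorical features such as hospitalization status).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from ._genetic_code import SENSE_CODONS, translate
from .errors import EmptyInputError, ValidationError, ValidationWarning

#: Canonical per-clonotype columns, in output order.
CANONICAL_COLUMNS = ["count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j"]

#: Sentinel for missing segment assignments, kept as its own usage category.
UNRESOLVED = "unresolved"

#: If a supplied freq column sums to 1 within this, it is kept verbatim.
FREQ_SUM_TOL = 1e-3


class ClonotypeRecord(NamedTuple):
    count: int
    freq: float
    cdr3nt: str
    cdr3aa: str
    v: str
    d: str
    j: str
    sample: str


def canonicalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a raw clonotype frame (see module docs)."""
    df = df.copy()
    if "count" not in df.columns:
        raise ValidationError("clonotype frame has no 'count' column")

    df["count"] = pd.to_numeric(df["count"], errors="coerce")
    df = df[df["count"].notna() & (df["count"] >= 1)]
    if len(df) == 0:
        raise EmptyInputError("no usable clonotype rows (all counts missing or < 1)")
    df["count"] = df["count"].round().astype(np.int64)

    for col in ("cdr3nt", "cdr3aa"):
        if col not in df.columns:
            raise ValidationError(f"clonotype frame has no '{col}' column")
        df[col] = df[col].astype(str).str.strip().str.upper()
    nonempty = (df["cdr3nt"] != "") & (df["cdr3aa"] != "")
    if not nonempty.all():
        warnings.warn(
            f"dropped {(~nonempty).sum()} rows with empty CDR3 sequence",
            ValidationWarning, stacklevel=2,
        )
        df = df[nonempty]
        if len(df) == 0:
            raise EmptyInputError("no usable clonotype rows (empty CDR3 sequences)")

    bad_nt = ~df["cdr3nt"].str.fullmatch("[ACGT]+")
    if bad_nt.any():
        warnings.warn(
            f"{bad_nt.sum()} cdr3nt values contain non-ACGT characters",
            ValidationWarning, stacklevel=2,
        )
    noncoding = df["cdr3aa"].str.contains(r"[*_]", regex=True)
    if noncoding.any():
        warnings.warn(
            f"{noncoding.sum()} cdr3aa values look non-coding ('*' or '_'); "
            "inputs are expected to be filtered upstream — rows retained",
            ValidationWarning, stacklevel=2,
        )

    for col in ("v", "d", "j"):
        if col not in df.columns:
            df[col] = UNRESOLVED
        else:
            df[col] = df[col].fillna(UNRESOLVED).astype(str).str.strip()
            df.loc[df[col].isin(("", "nan", "NaN", ".", "NA")), col] = UNRESOLVED

    had_freq = "freq" in df.columns
    if had_freq:
        df["freq"] = pd.to_numeric(df["freq"], errors="coerce")

    # Merge duplicate clonotypes; cdr3aa is determined by cdr3nt, keep first.
    agg = {"count": "sum", "cdr3aa": "first"}
    if had_freq:
        agg["freq"] = "sum"
    df = (
        df.groupby(["cdr3nt", "v", "d", "j"], as_index=False, sort=False)
        .agg(agg)
    )

    total = int(df["count"].sum())
    if (not had_freq or df["freq"].isna().any()
            or abs(float(df["freq"].sum()) - 1.0) > FREQ_SUM_TOL):
        df["freq"] = df["count"] / total

    df = df.sort_values(
        ["count", "cdr3nt"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df[CANONICAL_COLUMNS]


class RepertoireTable:
    """One sample's canonicalized clonotype table."""

    __slots__ = ("sample", "df")

    def __init__(self, sample: str, df: pd.DataFrame, *, canonicalize: bool = True):
        if not sample:
            raise ValidationError("sample identifier must be non-empty")
        self.sample = str(sample)
        self.df = canonicalize_frame(df) if canonicalize else df.reset_index(drop=True)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_records(cls, sample: str, records: Iterable[dict]) -> "RepertoireTable":
        return cls(sample, pd.DataFrame(list(records)))

    @classmethod
    def from_counts(
        cls,
        sample: str,
        counts: Sequence[int],
        *,
        cdr3nt: Optional[Sequence[str]] = None,
        cdr3aa: Optional[Sequence[str]] = None,
        v: Optional[Sequence[str]] = None,
        d: Optional[Sequence[str]] = None,
        j: Optional[Sequence[str]] = None,
    ) -> "RepertoireTable":
        """Build a small table from counts, filling deterministic sequences.

        Convenience constructor for examples and tests: row ``i`` gets a
        unique in-frame CDR3 built from sense codons unless sequences are
        supplied explicitly.
        """
        n = len(counts)
        if cdr3nt is None:
            digit_codons = ["GCT", "TGT", "GAT", "GAA", "TTT",
                            "GGT", "CAT", "ATT", "AAA", "CTG"]
            cdr3nt = [
                "TGTGCC" + "".join(digit_codons[int(ch)] for ch in f"{i:03d}") + "TTT"
                for i in range(n)
            ]
        if cdr3aa is None:
            cdr3aa = [translate(s) if len(s) % 3 == 0 else "X" for s in cdr3nt]
        frame = pd.DataFrame({
            "count": list(counts),
            "cdr3nt": list(cdr3nt),
            "cdr3aa": list(cdr3aa),
            "v": list(v) if v is not None else ["TRBV1"] * n,
            "d": list(d) if d is not None else ["TRBD1"] * n,
            "j": list(j) if j is not None else ["TRBJ1"] * n,
        })
        return cls(sample, frame)

    # -- accessors --------------------------------------------------------

    @property
    def n(self) -> int:
        """Number of distinct clonotypes."""
        return len(self.df)

    @property
    def total_reads(self) -> int:
        return int(self.df["count"].sum())

    @property
    def counts(self) -> np.ndarray:
        return self.df["count"].to_numpy()

    @property
    def freqs(self) -> np.ndarray:
        return self.df["freq"].to_numpy()

    def records(self) -> list[ClonotypeRecord]:
        return [
            ClonotypeRecord(int(r.count), float(r.freq), r.cdr3nt, r.cdr3aa,
                            r.v, r.d, r.j, self.sample)
            for r in self.df.itertuples(index=False)
        ]

    def to_frame(self, include_sample: bool = True) -> pd.DataFrame:
        out = self.df.copy()
        if include_sample:
            out["sample"] = self.sample
        return out

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return (isinstance(other, RepertoireTable)
                and self.sample == other.sample and self.df.equals(other.df))

    def __repr__(self) -> str:
        return (f"RepertoireTable(sample={self.sample!r}, clonotypes={self.n}, "
                f"reads={self.total_reads})")


class CohortDataset:
    """Many repertoires plus optional per-sample metadata features."""

    __slots__ = ("tables", "metadata")

    def __init__(self, tables: dict[str, RepertoireTable],
                 metadata: Optional[pd.DataFrame] = None):
        self.tables = dict(tables)
        self.metadata = metadata

    @classmethod
    def from_long(cls, df: pd.DataFrame,
                  metadata: Optional[pd.DataFrame] = None) -> "CohortDataset":
        """Build from a long-format frame with a ``sample`` column."""
        if "sample" not in df.columns:
            raise ValidationError("long-format cohort frame needs a 'sample' column")
        tables = {
            str(s): RepertoireTable(str(s), sub.drop(columns="sample"))
            for s, sub in df.groupby("sample", sort=True)
        }
        return cls(tables, metadata)

    @property
    def samples(self) -> list[str]:
        return list(self.tables)

    def __len__(self) -> int:
        return len(self.tables)

    def __iter__(self) -> Iterator[RepertoireTable]:
        return iter(self.tables.values())

    def __getitem__(self, sample: str) -> RepertoireTable:
        return self.tables[sample]

    def to_long(self) -> pd.DataFrame:
        if not self.tables:
            return pd.DataFrame(columns=CANONICAL_COLUMNS + ["sample"])
        return pd.concat(
            [t.to_frame() for t in self.tables.values()], ignore_index=True
        )

    def feature_values(self, feature: str) -> pd.Series:
        """Per-sample values of one metadata feature, indexed by sample."""
        if self.metadata is None:
            raise ValidationError("cohort has no metadata")
        if feature not in self.metadata.columns:
            raise ValidationError(
                f"feature {feature!r} not in metadata "
                f"(have: {', '.join(self.metadata.columns)})"
            )
        return self.metadata.loc[list(self.tables), feature]

    def __repr__(self) -> str:
        meta = "none" if self.metadata is None else f"{self.metadata.shape[1]} features"
        return f"CohortDataset(samples={len(self)}, metadata={meta})"
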