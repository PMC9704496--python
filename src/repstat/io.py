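"""Reading, converting, and writing clonotype tables and metadata.

Supported input dialects:

``canonical``
    The native schema: ``count`` (or ``#count``), ``freq``, ``cdr3nt``,
    ``cdr3aa``, ``v``, ``d``, ``j`` and optionally ``sample``.
``mixcr``
    MiXCR clone tables (``cloneCount``, ``cloneFraction``, ``nSeqCDR3``,
    ``aaSeqCDR3``, ``bestVHit``/``bestDHit``/``bestJHit``).
``immunoseq``
    Adaptive ImmunoSEQ exports (``templates``, ``rearrangement``,
    ``amino_acid``, ``v_resolved``/``d_resolved``/``j_resolved``).

A custom :class:`DialectSpec` absorbs vendor drift: any mapping covering at
least ``count`` and one CDR3 sequence column is accepted. When ``cdr3aa`` is
absent it is derived by standard-genetic-code translation of ``cdr3nt``.

Delimiters are inferred from the file extension (``.csv`` → comma, anything
else → tab) unless given explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from ._genetic_code import translate
from .containers import (CANONICAL_COLUMNS, CohortDataset, RepertoireTable)
from .errors import EmptyInputError, SchemaError, ValidationError, ValidationWarning


@dataclass(frozen=True)
class DialectSpec:
    """Mapping from a source column layout to the canonical schema."""

    name: str
    column_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        mapped = set(self.column_map.values())
        if "count" not in mapped or not ({"cdr3nt", "cdr3aa"} & mapped):
            raise SchemaError(
                f"dialect {self.name!r} must map 'count' and at least one of "
                "'cdr3nt'/'cdr3aa'"
            )


DIALECTS: dict[str, DialectSpec] = {
    "canonical": DialectSpec("canonical", {
        "#count": "count", "count": "count", "freq": "freq",
        "frequency": "freq", "cdr3nt": "cdr3nt", "cdr3aa": "cdr3aa",
        "v": "v", "d": "d", "j": "j", "sample": "sample",
    }),
    "mixcr": DialectSpec("mixcr", {
        "cloneCount": "count", "cloneFraction": "freq",
        "nSeqCDR3": "cdr3nt", "aaSeqCDR3": "cdr3aa",
        "bestVHit": "v", "bestDHit": "d", "bestJHit": "j",
        "sample": "sample",
    }),
    "immunoseq": DialectSpec("immunoseq", {
        "templates": "count", "productive_frequency": "freq",
        "frequency": "freq", "rearrangement": "cdr3nt",
        "amino_acid": "cdr3aa", "v_resolved": "v", "d_resolved": "d",
        "j_resolved": "j", "sample_name": "sample", "sample": "sample",
    }),
}


def get_dialect(dialect: Union[str, DialectSpec]) -> DialectSpec:
    if isinstance(dialect, DialectSpec):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise SchemaError(
            f"unknown dialect {dialect!r} (known: {', '.join(DIALECTS)})"
        ) from None


def _delimiter_for(path: Path, delimiter: Optional[str]) -> str:
    if delimiter:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_raw(path, dialect, delimiter) -> pd.DataFrame:
    path = Path(path)
    spec = get_dialect(dialect)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    df.columns = [str(c).strip() for c in df.columns]
    rename = {src: dst for src, dst in spec.column_map.items() if src in df.columns}
    df = df.rename(columns=rename)
    # keep first occurrence if two source columns map to the same target
    df = df.loc[:, ~df.columns.duplicated()]
    keep = [c for c in CANONICAL_COLUMNS + ["sample"] if c in df.columns]
    df = df[keep]
    if "count" not in df.columns:
        raise SchemaError(
            f"{path.name}: missing mandatory column 'count' "
            f"(dialect {spec.name!r})"
        )
    if "cdr3nt" not in df.columns:
        if "cdr3aa" in df.columns:
            raise SchemaError(
                f"{path.name}: missing mandatory column 'cdr3nt' "
                "(amino-acid-only tables are not supported)"
            )
        raise SchemaError(f"{path.name}: missing mandatory column 'cdr3nt'")
    if len(df) == 0:
        raise EmptyInputError(f"{path.name}: zero usable rows")
    if "cdr3aa" not in df.columns:
        df["cdr3aa"] = [translate(s) for s in df["cdr3nt"].astype(str).str.upper()]
    return df


def read_clonotype_table(
    path,
    dialect: Union[str, DialectSpec] = "canonical",
    sample: Optional[str] = None,
    delimiter: Optional[str] = None,
) -> RepertoireTable:
    """Read one sample's clonotype table and return the canonical form.

    ``sample`` names the repertoire; if omitted, a single-valued ``sample``
    column in the file is used instead. Files holding several samples must
    go through :func:`read_cohort`.
    """
    df = _read_raw(path, dialect, delimiter)
    if sample is None:
        if "sample" in df.columns:
            uniques = df["sample"].astype(str).unique()
            if len(uniques) > 1:
                raise ValidationError(
                    f"{Path(path).name} holds {len(uniques)} samples; "
                    "use read_cohort()"
                )
            sample = uniques[0]
        else:
            raise ValidationError(
                "no sample id: pass sample=... or include a 'sample' column"
            )
    return RepertoireTable(sample, df.drop(columns="sample", errors="ignore"))


def read_cohort(
    path,
    dialect: Union[str, DialectSpec] = "canonical",
    metadata=None,
    delimiter: Optional[str] = None,
) -> CohortDataset:
    """Read a multi-sample clonotype file (requires a ``sample`` column)."""
    df = _read_raw(path, dialect, delimiter)
    if "sample" not in df.columns:
        raise SchemaError(f"{Path(path).name}: multi-sample read needs a 'sample' column")
    tables = [
        RepertoireTable(str(s), sub.drop(columns="sample"))
        for s, sub in df.groupby("sample", sort=True)
    ]
    if metadata is not None and not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    return merge_cohort(tables, metadata)


def read_metadata(path, delimiter: Optional[str] = None) -> pd.DataFrame:
    """Read the sample → features table; ``sample`` column is mandatory."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    df.columns = [str(c).strip() for c in df.columns]
    if "sample" not in df.columns:
        raise SchemaError(f"{path.name}: metadata must have a 'sample' column")
    df["sample"] = df["sample"].astype(str)
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dupes}")
    return df.set_index("sample")


def merge_cohort(
    tables: Iterable[RepertoireTable],
    metadata: Optional[pd.DataFrame] = None,
) -> CohortDataset:
    """Combine per-sample tables (+ optional metadata) into one cohort.

    Metadata rows for samples absent from the tables are dropped with a
    warning; samples missing from supplied metadata are an error, because
    downstream group comparisons would silently lose them.
    """
    table_map: dict[str, RepertoireTable] = {}
    for t in tables:
        if t.sample in table_map:
            raise ValidationError(f"duplicate sample id {t.sample!r}")
        table_map[t.sample] = t

    if metadata is not None:
        extra = [s for s in metadata.index if s not in table_map]
        if extra:
            warnings.warn(
                f"metadata rows without clonotype tables dropped: {extra}",
                ValidationWarning, stacklevel=2,
            )
            metadata = metadata.drop(index=extra)
        orphans = [s for s in table_map if s not in metadata.index]
        if orphans:
            raise ValidationError(
                f"samples missing from metadata: {orphans}"
            )
    return CohortDataset(table_map, metadata)


def write_table(obj, path, format: Optional[str] = None) -> Path:
    """Write a repertoire, cohort, or plain DataFrame as TSV/CSV.

    Round-trip property: reading the written file reproduces the canonical
    fields exactly (pandas writes shortest-roundtrip float representations).
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if format not in ("tsv", "csv"):
        raise ValidationError(f"unknown format {format!r} (use 'tsv' or 'csv')")
    sep = "," if format == "csv" else "\t"

    if isinstance(obj, RepertoireTable):
        frame = obj.to_frame()
    elif isinstance(obj, CohortDataset):
        frame = obj.to_long()
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise ValidationError(f"cannot write object of type {type(obj).__name__}")
    try:
        frame.to_csv(path, sep=sep, index=False)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path


def write_metadata(metadata: pd.DataFrame, path, format: Optional[str] = None) -> Path:
    return write_table(metadata.reset_index(), path, format)
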