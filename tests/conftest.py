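"""Shared fixtures: deterministic random clonotype tables for oracle checks."""

import numpy as np
import pytest

from repstat import RepertoireTable
from repstat._genetic_code import translate

# Clonotype pool the random tables draw from. Lengths vary (6/9/12 nt) and
# two synonymous nt pairs encode the same amino acids, so convergence,
# spectratype, and aa-keyed overlaps are all exercised.
_NTS = [
    "TGTGCAAGC", "TGCGCAAGC",            # both translate to CAS
    "TGTAGC", "TGCAGC",                  # both CS
    "TGTGCCAGCAGC", "TGTGCCAGCTTT",
    "TGTGATAGC", "TGTGAAAGC",
    "TGTGGTCATAGC", "TGTATTAAAAGC",
    "TGTCTGAGC", "TGTTTTAGC",
]
_VS = ["TRBV02-01*01", "TRBV09-01*01", "TRBV20-01*01"]
_DS = ["TRBD01-01*01", "unresolved"]
_JS = ["TRBJ1-01*01", "TRBJ2-07*01"]

POOL = [
    {"cdr3nt": nt, "cdr3aa": translate(nt),
     "v": _VS[i % len(_VS)], "d": _DS[i % len(_DS)], "j": _JS[i % len(_JS)]}
    for i, nt in enumerate(_NTS)
]


def random_table(rng: np.random.Generator, sample: str = "S",
                 max_n: int = 8) -> RepertoireTable:
    """A random small repertoire drawn from the shared clonotype pool."""
    n = int(rng.integers(1, max_n + 1))
    idx = rng.choice(len(POOL), size=n, replace=False)
    records = []
    for i in idx:
        rec = dict(POOL[int(i)])
        rec["count"] = int(rng.integers(1, 10))
        records.append(rec)
    return RepertoireTable.from_records(sample, records)


def record_dicts(table: RepertoireTable) -> list[dict]:
    """Canonical records as plain dicts, the form the oracles consume."""
    return [r._asdict() for r in table.records()]


@pytest.fixture
def rng():
    return np.random.default_rng(954078)


@pytest.fixture
def table_631():
    """The running example: counts (6, 3, 1), freqs (0.6, 0.3, 0.1)."""
    return RepertoireTable.from_counts("S1", [6, 3, 1])
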