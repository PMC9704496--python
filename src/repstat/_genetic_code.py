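"""Standard genetic code: codon table, translation, sense-codon list."""

from .errors import ValidationError

_BASES = "TCAG"
# Standard code, NCBI table 1, in TCAG nested order.
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

GENETIC_CODE: dict[str, str] = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}

STOP = "*"

#: The 61 codons that code for an amino acid.
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in GENETIC_CODE.items() if aa != STOP)
)


def translate(nt: str) -> str:
    """Translate an in-frame DNA string to amino acids.

    Raises ValidationError if the length is not a multiple of 3 or a
    codon contains characters outside ACGT.
    """
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValidationError(
            f"cannot translate cdr3nt of length {len(nt)} (not a codon multiple): {nt!r}"
        )
    try:
        return "".join(GENETIC_CODE[nt[i:i + 3]] for i in range(0, len(nt), 3))
    except KeyError as exc:
        raise ValidationError(f"invalid codon {exc} in {nt!r}") from None
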