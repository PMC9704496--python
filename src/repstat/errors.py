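"""Exception and warning types shared across the package."""


class RepstatError(Exception):
    """Base class for all repstat errors."""


class SchemaError(RepstatError):
    """A required column is missing or a dialect mapping is invalid."""


class EmptyInputError(RepstatError):
    """No usable rows remain after parsing/validation."""


class ValidationError(RepstatError):
    """Input values violate a documented invariant or precondition."""


class ValidationWarning(UserWarning):
    """Non-fatal data quality issue (e.g. non-coding CDR3 retained)."""
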