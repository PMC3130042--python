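"""Exception hierarchy for the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, ParseError/SchemaError/
ValidationError -> 3, numerical errors (UndefinedTestError, CollinearityError,
DegenerateFactorError, InvalidInputError) -> 4.
"""


class MetapqtlError(Exception):
    """Base class for all package errors."""


class ConfigError(MetapqtlError):
    """Invalid configuration (simulation or run config)."""


class ParseError(MetapqtlError):
    """Malformed input file (ragged rows, bad numbers); message carries line info."""


class SchemaError(MetapqtlError):
    """File parsed but required columns/variables are missing."""


class ValidationError(MetapqtlError):
    """Values present but invalid (e.g. unknown genotype string)."""


class DimensionError(MetapqtlError):
    """Mismatched sample counts between tables."""


class DegenerateFactorError(MetapqtlError):
    """A factor fit collapsed (all seed peptides excluded, or no usable seeds)."""


class UndefinedTestError(MetapqtlError):
    """Association test undefined (constant genotype, too few samples)."""


class CollinearityError(MetapqtlError):
    """Rank-deficient design matrix; message names the offending columns."""


class InvalidInputError(MetapqtlError):
    """Invalid data for a model fit (e.g. one-class outcome)."""
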