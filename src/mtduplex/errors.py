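"""Typed exceptions used across the pipeline.

Exit-code convention for the CLI: 0 success, 2 validation/configuration,
3 data integrity.
"""


class MtDuplexError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(MtDuplexError):
    """Malformed input file (FASTA/TSV/VCF)."""

    exit_code = 2


class ConfigurationError(MtDuplexError):
    """Invalid or infeasible configuration."""

    exit_code = 2


class ValidationError(MtDuplexError):
    """Invalid in-memory inputs (duplicate events, unsorted variants, ...)."""

    exit_code = 2


class DataConsistencyError(MtDuplexError):
    """Cross-source contradiction, e.g. conflicting reference alleles."""

    exit_code = 3


class IntegrityError(MtDuplexError):
    """Packaged fixture fails its checksum."""

    exit_code = 3


class HaplogroupLookupError(MtDuplexError):
    """Unknown haplogroup label."""

    exit_code = 2


class UndefinedStatisticError(MtDuplexError):
    """A statistic is undefined for the given input (zero cross-cell odds
    ratio, zero-variance paired t-test) and no silent correction is applied."""

    exit_code = 2
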