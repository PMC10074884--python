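"""Exception hierarchy shared across the package."""


class CodonOptimError(Exception):
    """Base class for all package errors."""


class AlphabetError(CodonOptimError):
    """A sequence contains a symbol outside the expected alphabet."""


class InvalidCDSError(CodonOptimError):
    """A nucleotide sequence is not a valid coding sequence."""


class ParseError(CodonOptimError):
    """A file could not be parsed."""


class ConfigError(CodonOptimError):
    """An invalid configuration value was supplied."""


class DataError(CodonOptimError):
    """Inconsistent or empty data passed to an operation."""


class DegenerateUsageError(CodonOptimError):
    """A codon-usage table has zero mass in a required synonymous family."""


class UndefinedMetricError(CodonOptimError):
    """A metric is undefined for the given input (e.g. nothing scorable)."""


class FormatError(CodonOptimError):
    """A model archive is corrupted or has an unexpected layout."""
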