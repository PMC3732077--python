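"""Exception hierarchy shared across the package.

Each error class carries a process exit code so the command-line layer can
translate failures into a stable scripting contract:
0 success, 2 configuration, 3 format/validation, 4 insufficient data.
"""


class ExofragError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(ExofragError):
    """Invalid run configuration: bad parameter values, missing files, bad labels."""

    exit_code = 2


class FormatError(ExofragError):
    """A table could not be parsed: missing columns, wrong dialect."""

    exit_code = 3


class ValidationError(ExofragError):
    """A parsed record violates a data invariant (named in the message)."""

    exit_code = 3


class InsufficientDataError(ExofragError):
    """Too few records to compute the requested statistic."""

    exit_code = 4


class UndefinedResultError(ExofragError):
    """The requested quantity is undefined on this input (e.g. zero denominator)."""

    exit_code = 4


class GenerationError(ExofragError):
    """The synthetic-data generator could not satisfy its constraints."""

    exit_code = 3
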