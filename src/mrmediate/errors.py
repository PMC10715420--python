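"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses)
to exit code 3.
"""


class MRMediateError(Exception):
    """Base class for all package errors."""


class ConfigError(MRMediateError):
    """Invalid or incomplete configuration."""


class DataError(MRMediateError):
    """Invalid, empty, or inconsistent input data."""


class FormatError(DataError):
    """A required column is missing or a file is malformed."""


class EmptyInputError(DataError):
    """No valid rows survived validation."""


class HarmonizationError(DataError):
    """Exposure and outcome tables share no usable variants."""
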