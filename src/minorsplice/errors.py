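"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to exit code 2 on the command line, ``DataError``
(and subclasses) to exit code 3.
"""


class MinorspliceError(Exception):
    """Base class for all package errors."""


class ConfigError(MinorspliceError):
    """Invalid configuration, parameters, or missing input files."""


class DataError(MinorspliceError):
    """Malformed or inconsistent input data."""


class GTFParseError(DataError):
    """A GTF line could not be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"GTF parse error at line {lineno}: {message}")


class ValidationError(DataError):
    """Structurally valid input violating a model invariant."""
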