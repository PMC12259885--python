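"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses)
to exit code 3.
"""


class DefensomeError(Exception):
    """Base class for all package errors."""


class ConfigError(DefensomeError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class DataError(DefensomeError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


class SchemaError(DataError):
    """A tabular input is missing a required column or has a bad header."""


class RecordError(DataError):
    """A single record violates an invariant; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CrossRefError(DataError):
    """A record references an entity (gene, contig, spacer) that does not exist."""


class PipelineError(DefensomeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
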