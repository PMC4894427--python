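"""Exception hierarchy for metadiv."""


class MetadivError(Exception):
    """Base class for all package errors."""


class FormatError(MetadivError):
    """A table violates its declared schema (duplicate ids, bad header...)."""


class ParseError(MetadivError):
    """A cell or line could not be parsed; carries coordinates when known."""

    def __init__(self, message, line=None, column=None):
        self.line = line
        self.column = column
        loc = ""
        if line is not None:
            loc += f" (line {line}"
            loc += f", column {column})" if column is not None else ")"
        super().__init__(message + loc)


class CrossReferenceError(MetadivError):
    """Identifiers in one table are missing from the table they reference."""


class ConfigError(MetadivError):
    """Invalid simulation or pipeline configuration."""


class DegenerateDataError(MetadivError):
    """Input carries no usable variation (e.g. a constant trait)."""
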