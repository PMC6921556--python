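"""Exception hierarchy.

``ValidationError`` covers bad inputs and configuration (CLI exit code 1);
every other :class:`NidynError` is a runtime failure (exit code 2).
"""


class NidynError(Exception):
    """Base class for all package errors."""


class ValidationError(NidynError):
    """Invalid input data, parameters or configuration."""


class SizingError(ValidationError):
    """A genome/window layout that cannot fit the requested features."""


class ParseError(ValidationError):
    """Malformed record in an input file; carries the 1-based line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
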