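"""Exception hierarchy shared across the package."""


class PathsparseError(Exception):
    """Base class for all package errors."""


class ParseError(PathsparseError):
    """A malformed input file (carries the offending line number when known)."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)


class StructuralError(PathsparseError):
    """A structurally invalid object (cycle, empty graph, shape mismatch)."""


class ConfigurationError(PathsparseError):
    """An invalid configuration value."""


class ValidationError(PathsparseError):
    """Input data violating a documented value contract."""
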