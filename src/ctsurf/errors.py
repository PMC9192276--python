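"""Exception hierarchy.

All errors derive from :class:`CtsurfError` so callers can catch the package's
failures with a single except clause; each subclass also inherits the builtin
exception users would expect (``ValueError`` for bad parameters and inputs).
"""


class CtsurfError(Exception):
    """Base class for all ctsurf errors."""


class InvalidParameterError(CtsurfError, ValueError):
    """A numeric or structural parameter violates an operation's precondition."""


class InvalidInputError(CtsurfError, ValueError):
    """An input object (grid, mesh, contour set) is malformed or inconsistent."""


class UndefinedMetricError(CtsurfError, ZeroDivisionError):
    """A diagnostic metric has an empty denominator.

    The offending metric's name is stored in :attr:`metric`.
    """

    def __init__(self, metric: str, message: str | None = None):
        self.metric = metric
        super().__init__(message or f"metric '{metric}' is undefined (empty denominator)")


class MeshParseError(CtsurfError, ValueError):
    """A mesh file could not be parsed.

    Carries the 1-based line number (text formats) or byte offset (binary STL)
    at which parsing failed.
    """

    def __init__(self, message: str, *, line: int | None = None, offset: int | None = None):
        self.line = line
        self.offset = offset
        where = f" (line {line})" if line is not None else (
            f" (byte offset {offset})" if offset is not None else "")
        super().__init__(message + where)


class MeshFormatError(CtsurfError, ValueError):
    """Unknown or unsupported mesh file format."""
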