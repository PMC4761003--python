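"""Exception hierarchy.

Everything raised on purpose derives from :class:`ShrnascanError` so callers
(and the CLI batch loop) can distinguish expected per-query failures from
programming errors.
"""


class ShrnascanError(Exception):
    """Base class for all package errors."""


class PatternSyntaxError(ShrnascanError, ValueError):
    """The siRNA-locating pattern expression is malformed."""


class NoSiteError(ShrnascanError):
    """No flank match in either orientation of a clone read."""

    def __init__(self, read_name: str, message: str | None = None):
        self.read_name = read_name
        super().__init__(message or f"no hairpin site found in read {read_name!r}")


class TruncatedCaptureError(ShrnascanError):
    """A capture window runs past the end of the read."""

    def __init__(self, read_name: str, message: str | None = None):
        self.read_name = read_name
        super().__init__(
            message or f"capture window runs past the end of read {read_name!r}"
        )


class EmptyInputError(ShrnascanError, ValueError):
    """An operation received an empty sequence."""


class ParameterError(ShrnascanError, ValueError):
    """A numeric or mode parameter is out of its allowed range."""


class DatabaseError(ShrnascanError):
    """Transcript database unreadable or empty after filtering."""


class SchemaError(ShrnascanError, ValueError):
    """A tabular input file does not match its required schema."""

    def __init__(self, message: str, missing: list[str] | None = None):
        self.missing = missing or []
        super().__init__(message)


class InsufficientReplicatesError(ShrnascanError, ValueError):
    """A statistical group has fewer than two values."""


class AmbiguousQueryError(ShrnascanError):
    """A duplex flagged for ambiguous bases was submitted to the search."""
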