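"""Exception hierarchy shared across the package.

All errors derive from :class:`CtgrSpanError` so callers can catch one base
class; most also derive from ``ValueError`` for ergonomic use in scripts.
"""


class CtgrSpanError(Exception):
    """Base class for every error raised by this package."""


class FormatError(CtgrSpanError, ValueError):
    """A table or file does not conform to the expected dialect."""


class ParseError(FormatError):
    """A malformed token in a text input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateRecordError(FormatError):
    """The same key (e.g. patient/gene row) appears more than once."""


class DomainError(CtgrSpanError, ValueError):
    """A value lies outside the mathematically admissible domain."""


class ParameterError(CtgrSpanError, ValueError):
    """A user-supplied parameter violates its documented range."""


class FixtureLookupError(CtgrSpanError, KeyError):
    """An unknown bundled-fixture name was requested."""


class SizeError(CtgrSpanError, ValueError):
    """An exhaustive computation was asked to run on too large an input."""


class ConfigError(CtgrSpanError, ValueError):
    """A synthetic-data configuration is internally inconsistent."""
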