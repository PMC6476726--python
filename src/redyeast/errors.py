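"""Exception hierarchy shared across the package."""


class RedyeastError(Exception):
    """Base class for all package errors."""


class FormatError(RedyeastError, ValueError):
    """A file does not conform to its declared format.

    Messages include the offending line number where one exists.
    """


class DataError(RedyeastError, ValueError):
    """Input values are syntactically valid but scientifically impossible
    (e.g. a non-positive Ct)."""


class UsageError(RedyeastError, ValueError):
    """An operation was called with arguments that violate its contract
    (e.g. mixed scaffold pairs passed to a single-pair chainer)."""


class InternalError(RedyeastError, RuntimeError):
    """An internal invariant was violated; indicates a bug, not bad input."""
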