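"""Exception hierarchy used across the package.

All errors derive from :class:`SvagreeError` so callers can catch the
package's failures with a single except clause.  ``InvalidArgumentError``
also derives from :class:`ValueError` for compatibility with generic code.
"""


class SvagreeError(Exception):
    """Base class for all svagree errors."""


class InvalidArgumentError(SvagreeError, ValueError):
    """An argument violates a documented precondition."""


class DataIntegrityError(SvagreeError):
    """Input data are internally inconsistent (e.g. overlapping periods)."""


class DataFormatError(DataIntegrityError):
    """A file or frame does not match the expected schema.

    Carries the offending column name in ``column`` when known.
    """

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class ModelSpecificationError(SvagreeError):
    """A model cannot be specified on the given data (rank deficiency,
    single subject, one sex only when an interaction is requested, ...)."""


class ConvergenceError(SvagreeError):
    """A mixed-model fit failed to converge.  ``diagnostics`` holds whatever
    the optimizer reported."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
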