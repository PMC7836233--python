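"""Exception hierarchy.

All errors derive from :class:`FoldmorphError` so callers can catch the
package's failures with one clause; subclasses distinguish schema problems
(wrong columns), parse problems (bad values), configuration problems
(invalid requests) and degenerate numerical situations.
"""


class FoldmorphError(Exception):
    """Base class for all foldmorph errors."""


class SchemaError(FoldmorphError):
    """A required column is missing or the table layout is wrong."""


class ParseError(FoldmorphError):
    """A cell could not be interpreted (e.g. non-numeric area)."""


class ValidationError(FoldmorphError):
    """Rows violate invariants; carries a per-row report."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class ConfigurationError(FoldmorphError):
    """An operation was requested with inconsistent or missing options."""


class DegenerateFitError(FoldmorphError):
    """A regression or decomposition has no unique solution."""


class DomainError(FoldmorphError, ValueError):
    """An argument is outside the mathematical domain of an operation."""
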