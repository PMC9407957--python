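"""Exception hierarchy for icessd.

All package-specific errors derive from :class:`IcessdError` so callers can
catch everything with one except clause while the CLI maps them to exit codes.
"""


class IcessdError(Exception):
    """Base class for all icessd errors."""


class SchemaError(IcessdError):
    """An input table is missing a required column."""


class ValidationError(IcessdError):
    """A row in an input table violates a domain invariant."""


class UnitError(IcessdError):
    """An unknown or inconsistent concentration unit was requested."""


class InsufficientDataError(IcessdError):
    """Too few observations for the requested fit or test."""


class DegenerateDesignError(IcessdError):
    """The design matrix (or value set) has no usable variation."""


class IncompleteTaxonomyError(IcessdError):
    """A taxonomic rank needed to decide relatedness is missing."""
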