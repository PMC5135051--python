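"""Exception hierarchy for the antweb pipeline.

All domain errors derive from :class:`AntwebError` so callers can catch the
whole family; schema/validation errors additionally derive from
:class:`ValueError` because they signal malformed user input.
"""


class AntwebError(Exception):
    """Base class for all antweb-specific errors."""


class SchemaError(AntwebError, ValueError):
    """An input table is missing required columns or uses unknown labels."""


class ValidationError(AntwebError, ValueError):
    """A record violates a field invariant (e.g. negative worker count)."""


class EmptyLayerError(AntwebError):
    """No interaction events remain after filtering; no matrix can be built."""


class UndefinedMetricError(AntwebError):
    """The metric is not defined on this matrix (e.g. a single row or column)."""


class DegenerateNullError(AntwebError):
    """The null distribution carries no variance; standardization is undefined."""


class DegenerateDesignError(AntwebError):
    """A statistical design has too few groups, replicates, or all-zero distances."""
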