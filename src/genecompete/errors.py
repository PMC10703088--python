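"""Exception hierarchy shared by all modules."""


class GeneCompeteError(Exception):
    """Base class for all package errors."""


class InputError(GeneCompeteError):
    """A required input file is missing or unreadable."""


class SchemaError(GeneCompeteError):
    """A required column is absent or malformed."""


class EmptyTableError(GeneCompeteError):
    """A table contained zero parsable rows."""


class EmptyCompetitionError(GeneCompeteError):
    """No candidate genes survive the strategy/filter."""


class DegenerateCompetitionError(GeneCompeteError):
    """Fewer than two genes available to compete."""


class ConvergenceError(GeneCompeteError):
    """An iterative solver failed to converge within its iteration cap."""


class UndefinedMetricError(GeneCompeteError):
    """A curve metric is undefined (no positives or no negatives)."""
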