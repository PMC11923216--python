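"""Exception hierarchy for the assessment pipeline.

Every stage raises a subclass of :class:`FairstockError` so the CLI can
report which stage failed without matching on message text.
"""


class FairstockError(Exception):
    """Base class for all package errors."""


class SchemaError(FairstockError):
    """Input table does not match the column dictionary."""


class KeyCollisionError(SchemaError):
    """Duplicate (dataset, round, respondent) key in an input table."""


class IntegrityError(FairstockError):
    """Contradictory rows that cannot be merged (same respondent, same round)."""


class ApplicabilityError(FairstockError):
    """A rubric was applied to a record outside its scope."""


class CompletenessError(FairstockError):
    """A summary was requested with scores missing for some datasets."""


class ConfigurationError(FairstockError):
    """Invalid generator/run configuration or missing reclassification rule."""


class DomainError(FairstockError, ValueError):
    """A value outside the mathematical domain of an operation."""
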