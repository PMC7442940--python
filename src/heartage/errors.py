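"""Exception hierarchy shared across the package."""


class HeartAgeError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(HeartAgeError, ValueError):
    """A caller-supplied value violates a precondition (e.g. nonpositive height)."""


class ConfigurationError(HeartAgeError, ValueError):
    """A coefficient set, imputation table or simulation config is inconsistent,
    or a profile lacks a covariate the active equation requires."""


class DegenerateTableError(HeartAgeError, ValueError):
    """A contingency table has an expected count of zero, so the Pearson
    statistic is undefined."""


class EmptyCohortError(HeartAgeError, ValueError):
    """A summary was requested for zero records."""


class SchemaError(HeartAgeError, ValueError):
    """An input file does not match the documented column schema."""
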