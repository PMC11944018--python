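"""Typed exceptions raised across the pipeline.

Every validation failure raises one of these rather than silently
coercing, so callers (and the CLI) can report which stage rejected
the input and why.
"""


class HormsenseError(Exception):
    """Base class for all package errors."""


class SchemaError(HormsenseError):
    """A required column is missing or has the wrong header."""


class ValidationError(HormsenseError):
    """A cell value violates a field invariant (range, sign, vocabulary)."""


class DesignError(HormsenseError):
    """The experimental design is unusable (no control group, one class absent)."""


class DuplicateError(ValidationError):
    """A key that must be unique appears more than once."""


class InsufficientReplicationError(DesignError):
    """A treatment group has fewer than two replicates."""


class FoldSchemeError(DesignError):
    """A cross-validation fold would leave a class absent from training."""


class DegenerateModelError(HormsenseError):
    """The fitted model explains no response variance (all SSY zero)."""


class ConvergenceError(HormsenseError):
    """NIPALS failed to converge within the iteration budget."""


class UndefinedBaselineError(ValidationError):
    """Control-group mean is zero or negative; percent change undefined."""


class UndefinedCorrelationError(ValidationError):
    """A correlation input vector has zero variance."""


class MappingError(HormsenseError):
    """A hormone has no pathway assignment in the hormone-pathway map."""


class ConfigError(HormsenseError):
    """A configuration field is invalid or inconsistent."""
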