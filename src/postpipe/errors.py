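"""Exception hierarchy shared across the pipeline.

Validation-type errors (bad input data, bad schema, bad configuration) map to
CLI exit code 1; anything else is an internal error (exit code 2).
"""


class PostpipeError(Exception):
    """Base class for all package errors."""


class SchemaError(PostpipeError):
    """Input file does not match the documented schema (missing column,
    wrong schema version, malformed header)."""


class CohortValidationError(PostpipeError):
    """A record violates a domain invariant."""

    def __init__(self, patient_id, field, message):
        self.patient_id = patient_id
        self.field = field
        super().__init__(f"patient {patient_id!r}, field {field!r}: {message}")


class InsufficientDataError(PostpipeError):
    """A criterion cannot be scored because required inputs are missing.

    Never silently scored as zero.
    """

    def __init__(self, patient_id, missing_fields):
        self.patient_id = patient_id
        self.missing_fields = list(missing_fields)
        super().__init__(
            f"patient {patient_id!r}: insufficient data for scoring, "
            f"missing fields: {', '.join(self.missing_fields)}"
        )


class UnclassifiedTransientError(PostpipeError):
    """Headache-naive patient with a post-procedural headache that does not
    meet the persistence/exclusion criteria: no outcome bucket exists for
    this case and it is surfaced for manual review instead of guessed."""

    def __init__(self, patient_id):
        self.patient_id = patient_id
        super().__init__(
            f"patient {patient_id!r}: transient new headache (criteria A/D not met); "
            "requires manual review"
        )


class SeparationError(PostpipeError):
    """Perfect separation detected in logistic regression."""

    def __init__(self, covariate):
        self.covariate = covariate
        super().__init__(f"perfect separation on covariate {covariate!r}")


class ConvergenceError(PostpipeError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        self.trace = trace or []
        super().__init__(message)


class ConfigurationError(PostpipeError):
    """Invalid configuration value."""
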