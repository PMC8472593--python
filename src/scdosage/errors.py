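"""Exception hierarchy.

Every validation failure raises a distinct, named error so callers (and the
CLI, which maps them to exit code 2) can tell malformed input apart from a
pipeline-stage failure.
"""


class ScdosageError(Exception):
    """Base class for all package errors."""


class ValidationError(ScdosageError):
    """Invalid input data or parameters."""


class MalformedHeaderError(ValidationError):
    """A tabular file's header row is missing or inconsistent."""


class DuplicateIdError(ValidationError):
    """A gene or cell identifier occurs more than once."""


class NegativeValueError(ValidationError):
    """An expression value (TPM or count) is negative."""


class NaNValueError(ValidationError):
    """An expression value is NaN or non-finite."""


class CoordinateError(ValidationError):
    """A genomic interval is empty, inverted, or has a negative coordinate."""


class OverlappingSegmentsError(ValidationError):
    """CNV segments of one patient self-overlap on a chromosome."""


class UnknownStateError(ValidationError):
    """An unrecognized copy-number state token."""


class MetadataError(ValidationError):
    """Cell metadata does not cover the expression matrix, or vice versa."""


class StageError(ScdosageError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
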