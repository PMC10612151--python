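"""Exception hierarchy shared across the package."""


class FusiformError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(FusiformError, ValueError):
    """A design parameter (length, width, angle) is outside its valid domain."""


class InfeasibleRatioError(FusiformError, ValueError):
    """A requested dimensionless ratio lies outside the model's attainable range."""


class InvalidCalibrationError(FusiformError, ValueError):
    """A photographic scale or reference-object value is zero, negative or missing."""


class CohortValidationError(FusiformError, ValueError):
    """One or more cohort records failed validation; message lists the offenders."""


class CohortSchemaError(FusiformError, ValueError):
    """A cohort CSV header does not match any known schema mode."""
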