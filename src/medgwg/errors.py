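"""Exception hierarchy for the medgwg pipeline.

Every stage raises a subclass of :class:`MedgwgError`; the CLI maps
validation errors to exit code 1 and runtime errors to exit code 2.
"""


class MedgwgError(Exception):
    """Base class for all package errors."""


class ConfigError(MedgwgError):
    """Invalid configuration; message names the offending field."""


class DomainError(MedgwgError):
    """Input outside the mathematical domain of an operation."""


class AgeRangeError(MedgwgError):
    """Requested age outside the growth-reference table's coverage."""


class SchemaError(MedgwgError):
    """Input file does not match the documented column schema."""


class FitError(MedgwgError):
    """Model fitting failed (separation, non-convergence, rank deficiency)."""


class ImputationError(MedgwgError):
    """A value could not be imputed (no usable neighbours / all-missing column)."""


class InferenceError(MedgwgError):
    """Bootstrap or pooling could not produce reliable intervals."""


class UnderweightExclusion(MedgwgError):
    """Signal that a mother falls below the BMI 18.5 eligibility floor.

    Raised by :func:`medgwg.anthropometry.classify_maternal_bmi`; the
    pipeline catches it, drops the record and logs the exclusion reason
    rather than aborting.
    """
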