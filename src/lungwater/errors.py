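"""Exception hierarchy with exit-code classes for the CLI.

Exit code classes: 2 usage, 3 format, 4 validation, 5 numeric.
"""


class LungWaterError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(LungWaterError):
    """Bad invocation: unknown flag, clobbering without --force, etc."""

    exit_code = 2


class FormatError(LungWaterError):
    """Unreadable or structurally wrong input file (garbled header, wrong rank,
    missing schema column)."""

    exit_code = 3


class ValidationError(LungWaterError):
    """Well-formed input with invalid content (bad values, duplicate ids,
    out-of-range parameters)."""

    exit_code = 4


class AlignmentError(ValidationError):
    """Volume and mask do not share shape/spacing; no resampling is attempted."""


class EmptySelectionError(ValidationError):
    """A voxel selection came back empty where a non-empty one is required."""


class NumericError(LungWaterError):
    """A computation is mathematically undefined on this input."""

    exit_code = 5


class IdentifiabilityError(NumericError):
    """Rank-deficient regression design (e.g. constant predictor)."""
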