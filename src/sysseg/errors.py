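"""Exception hierarchy shared across the pipeline stages."""


class SysSegError(Exception):
    """Base class for all package errors."""


class ValidationError(SysSegError, ValueError):
    """A specification or configuration field failed validation."""


class SchemaError(SysSegError, KeyError):
    """An input table is missing a required column."""


class DegenerateInputError(SysSegError, ValueError):
    """Input has no usable signal (constant block, zero-variance ROI, ...)."""


class InsufficientDataError(SysSegError, ValueError):
    """Fewer observations than model/design columns."""


class GenerationError(SysSegError, RuntimeError):
    """Synthetic-data generation failed (e.g. non-positive-definite target)."""


class UndefinedStatisticError(SysSegError, ZeroDivisionError):
    """A requested statistic is undefined for this input (e.g. W = 0)."""


class PartitionError(SysSegError, KeyError):
    """ROI/network bookkeeping between matrix and partition is inconsistent."""
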