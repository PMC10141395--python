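"""Exception hierarchy.

All package errors derive from :class:`MFPatchError` so callers can catch one
type; parameter/validation problems additionally derive from ``ValueError`` to
stay friendly to generic sklearn-style validation code.
"""


class MFPatchError(Exception):
    """Base class for all package errors."""


class ParameterError(MFPatchError, ValueError):
    """A parameter violates its documented constraints."""


class InputError(MFPatchError, ValueError):
    """An input series is malformed (non-finite sample, too short, ...)."""


class DegenerateSeriesError(MFPatchError, ValueError):
    """The series carries no usable fluctuation (e.g. locally deterministic)."""


class FitError(MFPatchError, RuntimeError):
    """A scaling fit could not be performed (too few usable scales)."""


class FormatError(MFPatchError, ValueError):
    """A recording or result file does not parse."""


class PipelineError(MFPatchError, RuntimeError):
    """An end-to-end analysis run failed (e.g. zero successful replicates)."""
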