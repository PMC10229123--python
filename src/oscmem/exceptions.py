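"""Exception hierarchy.

All library-specific failures derive from :class:`OscmemError` so callers can
catch one base class; precondition violations additionally derive from the
matching builtin (``ValueError``) to stay idiomatic.
"""


class OscmemError(Exception):
    """Base class for all oscmem errors."""


class ArgumentError(OscmemError, ValueError):
    """A function argument violates a documented precondition."""


class DataError(OscmemError, ValueError):
    """Input data is malformed (unknown labels, inverted intervals, ...)."""


class DegenerateTrialError(OscmemError, ValueError):
    """A behavioral trial has zero total exploration; DI is undefined."""


class FeatureError(OscmemError, ValueError):
    """A waveform/trace is degenerate and features cannot be computed."""


class EstimationError(OscmemError, RuntimeError):
    """A spectral estimate cannot be formed (too few windows/trials)."""


class FitError(OscmemError, RuntimeError):
    """Model fitting failed (all trials degenerate, non-convergence)."""


class GenerationError(OscmemError, RuntimeError):
    """Synthetic-data generation could not satisfy the request."""
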