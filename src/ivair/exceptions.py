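"""Exception hierarchy for ivair.

All package-specific failures derive from :class:`IvairError` so callers can
catch one type at the pipeline boundary while still distinguishing
configuration mistakes from data problems and numerical failures.
"""


class IvairError(Exception):
    """Base class for all ivair errors."""


class ConfigurationError(IvairError, ValueError):
    """An invalid configuration field (named in the message)."""


class ValidationError(IvairError, ValueError):
    """Input data violate the daily-series contract (offending rows named)."""


class DimensionError(IvairError, ValueError):
    """Array lengths or shapes do not align."""


class DegenerateDataError(IvairError, ValueError):
    """A covariate or response is constant / has no usable variation."""


class RankDeficiencyError(IvairError, ValueError):
    """A design matrix is rank deficient (offending columns listed)."""


class FitConvergenceError(IvairError, RuntimeError):
    """An iterative fit failed to converge within its iteration cap."""


class SelectionError(IvairError, RuntimeError):
    """Model selection (e.g. df search) found no admissible candidate."""


class InferenceError(IvairError, RuntimeError):
    """Resampling inference failed (e.g. too many replicate fit failures)."""
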