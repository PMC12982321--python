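"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`PhenoselectError`, so callers can catch the package's failures
without swallowing genuine bugs.
"""


class PhenoselectError(Exception):
    """Base class for all phenoselect errors."""


class FormatError(PhenoselectError):
    """A file does not conform to the expected delimited-text layout."""


class IntegrityError(PhenoselectError):
    """Data violate a structural invariant (date gaps, ordering, coverage)."""


class RangeError(PhenoselectError, ValueError):
    """A value lies outside its physically admissible range."""


class DegenerateDataError(PhenoselectError):
    """Input carries no usable variation (constant sample, all-zero rain)."""


class ParameterError(PhenoselectError, ValueError):
    """A configuration parameter is outside its admissible range."""


class ValidationError(PhenoselectError):
    """A model specification violates its family constraints."""


class CalibrationError(PhenoselectError):
    """Optimization failed to produce usable parameters."""

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class FitError(PhenoselectError):
    """A composite-model fit could not be performed."""


class SelectionError(PhenoselectError):
    """Model selection received unusable input."""


class ConfigurationError(PhenoselectError):
    """Required pieces of configuration are missing or inconsistent."""


class EvaluationError(PhenoselectError):
    """No valid prediction/observation pairs to score."""
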