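"""Exception hierarchy for filmrheo.

All filmrheo-raised errors derive from :class:`FilmRheoError` so callers can
catch the package's failures with a single except clause while still
distinguishing validation problems from numerical ones.
"""


class FilmRheoError(Exception):
    """Base class for all filmrheo errors."""


class ValidationError(FilmRheoError, ValueError):
    """An input record violates a type invariant (non-monotone time, bad strain, ...)."""


class FormatError(FilmRheoError, ValueError):
    """A delimited-text file cannot be parsed against the declared dialect."""


class DegenerateStepError(ValidationError):
    """A relaxation transient has no pressure response (pi_max == pi0)."""


class RangeError(FilmRheoError, ValueError):
    """A requested frequency band or area window lies outside the resolvable range."""


class OverlapError(FilmRheoError, ValueError):
    """Two isotherm branches share no common area range."""


class InsufficientResolutionError(FilmRheoError, ValueError):
    """A spectrum is too short for the requested analysis (e.g. peak counting)."""


class FitFailureError(FilmRheoError, RuntimeError):
    """The nonlinear fit did not converge; carries the best attempt found.

    Attributes
    ----------
    best_fit : MaxwellFit or None
        The lowest-cost fit among all restarts, even though it failed the
        convergence check.
    """

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class ConfigError(FilmRheoError, ValueError):
    """A run configuration is invalid or cannot be loaded."""
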