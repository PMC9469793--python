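"""Exception hierarchy shared across the package."""


class GammaloopError(Exception):
    """Base class for all package errors."""


class InvalidInputError(GammaloopError, ValueError):
    """Malformed or physically impossible input (wrong shape, rate, length...)."""


class StabilityError(GammaloopError, ValueError):
    """An operation that requires a (marginally) stable plant received an unstable one."""


class SingularModelError(GammaloopError, ZeroDivisionError):
    """The DC denominator 1 + sum(a) is numerically zero; steady state undefined."""


class SingularFrequencyError(GammaloopError, ValueError):
    """Theoretical PSD requested at f = 0, where the step-input term diverges."""


class InsufficientDataError(InvalidInputError):
    """Not enough samples to build the requested regression problem."""


class NonUniqueSolutionError(GammaloopError, ValueError):
    """Design matrix is rank deficient; the least-squares fit is not unique."""


class UnstableCompositeError(StabilityError):
    """Averaging per-trial models produced an unstable polynomial."""


class UnstabilizableError(GammaloopError, ValueError):
    """The (A, B) pair cannot be stabilized (no control authority)."""


class DegenerateTestError(GammaloopError, ValueError):
    """A statistical test was handed zero-variance data."""


class ConfigError(GammaloopError, ValueError):
    """Pipeline configuration violates a documented range or references missing files."""
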