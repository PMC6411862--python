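"""Exception types raised across the package."""


class KinesimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(KinesimError, ValueError):
    """A physical parameter is outside its admissible range."""


class ConfigValidationError(KinesimError, ValueError):
    """A configuration file failed validation.

    ``errors`` lists every offending key so a user can fix them all at once.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("configuration invalid:\n" + "\n".join(f"  - {e}" for e in self.errors))


class InsufficientDataError(KinesimError, ValueError):
    """Too few observations for the requested estimate."""


class FitFailureError(KinesimError, RuntimeError):
    """A nonlinear fit did not converge or the data are degenerate."""


class CorruptedStateError(KinesimError, RuntimeError):
    """Simulation state became non-finite (numerical blow-up)."""
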