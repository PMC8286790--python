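"""Exception hierarchy shared across the package."""


class SprQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(SprQuantError, ValueError):
    """A domain object or configuration value violates its invariants."""


class DipNotFoundError(SprQuantError, RuntimeError):
    """An angular scan has no interior reflectance minimum (range too narrow)."""


class CoverageModelError(SprQuantError, ValueError):
    """Measured response exceeds the modeled full-monolayer maximum."""


class SensorgramFormatError(SprQuantError, ValueError):
    """A sensorgram file is malformed (missing columns, non-monotone time)."""


class FitError(SprQuantError, RuntimeError):
    """Kinetic fit failed to converge; carries the best iterate found.

    Attributes
    ----------
    best : object or None
        Best parameter iterate reached before failure.
    diagnostic : str
        Solver message.
    """

    def __init__(self, message: str, best=None, diagnostic: str = ""):
        super().__init__(message)
        self.best = best
        self.diagnostic = diagnostic


class ConfigError(SprQuantError, ValueError):
    """Configuration file failed validation; carries all failures.

    Attributes
    ----------
    failures : list of str
        One entry per problem, each prefixed with the offending key path.
    """

    def __init__(self, failures):
        self.failures = list(failures)
        super().__init__(
            "configuration invalid:\n" + "\n".join(f"  - {f}" for f in self.failures)
        )
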