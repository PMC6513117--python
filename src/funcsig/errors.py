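"""Exception types shared across the package."""


class FuncsigError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FuncsigError, ValueError):
    """Invalid generator or run configuration."""


class InputError(FuncsigError, ValueError):
    """Malformed or insufficient input data (parse failures, too few units)."""


class NoRhythmicUnitsError(FuncsigError, ValueError):
    """Circadian QC removed every unit."""


class ZeroVarianceError(FuncsigError, ValueError):
    """A unit has zero variance, so Pearson correlation is undefined."""


class ConvergenceError(FuncsigError, RuntimeError):
    """An iterative procedure failed to converge within its iteration budget."""
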