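"""Exception hierarchy shared across the package."""


class DRScreenError(Exception):
    """Base class for all package errors."""


class ParameterError(DRScreenError, ValueError):
    """A simulation or cost-model parameter is invalid; names the field."""


class InputError(DRScreenError, ValueError):
    """Malformed analysis input (length mismatch, out-of-range code, ...)."""


class ConfigError(DRScreenError, ValueError):
    """Invalid sweep/report configuration (unknown strategy or parameter)."""


class AnalysisError(DRScreenError, RuntimeError):
    """An analysis stage cannot proceed (e.g. empty gradable set)."""


class UndefinedStatisticError(DRScreenError, ArithmeticError):
    """A statistic is undefined for the given data (Pe = 1, zero variance)."""
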