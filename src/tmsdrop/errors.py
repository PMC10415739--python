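"""Exception hierarchy shared across the package."""


class TmsdropError(Exception):
    """Base class for all package-specific errors."""


class InputError(TmsdropError, ValueError):
    """Invalid user-supplied value (concentration, count, window, ...)."""


class ConfigError(TmsdropError, ValueError):
    """Invalid or inconsistent configuration."""


class ParseError(TmsdropError, ValueError):
    """Malformed input file."""


class FitError(TmsdropError, RuntimeError):
    """A least-squares fit failed or the data cannot support one."""


class EmptyResultError(TmsdropError, RuntimeError):
    """An operation discarded or produced no data."""
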