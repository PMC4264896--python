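"""Exception hierarchy shared across the package."""


class ThermoperfError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ThermoperfError, ValueError):
    """Invalid configuration (generator settings, pipeline config, patch maps)."""


class FitError(ThermoperfError, RuntimeError):
    """A curve or model fit could not be completed."""


class ExtractionError(ThermoperfError, RuntimeError):
    """Biological parameters could not be extracted from a fitted curve."""


class ParseError(ThermoperfError, ValueError):
    """A data file violates the expected layout or ordering."""
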