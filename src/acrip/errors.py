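"""Exception hierarchy."""


class AcripError(Exception):
    """Base class for all package errors."""


class ConfigError(AcripError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(AcripError):
    """Malformed input file; the message carries the file and line/cell."""


class FitError(AcripError):
    """A model or curve fit failed or is degenerate."""
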