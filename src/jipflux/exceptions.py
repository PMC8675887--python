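"""Exception hierarchy for jipflux."""


class JipfluxError(Exception):
    """Base class for all jipflux errors."""


class FormatError(JipfluxError, ValueError):
    """A delimited input file does not have the expected layout."""


class ValidationError(JipfluxError, ValueError):
    """Input data violate an invariant (negative fluorescence, duplicate ids, ...)."""


class ExtractionError(JipfluxError, ValueError):
    """A transient does not span the landmarks requested for cardinal-point extraction."""


class DegenerateTransientError(JipfluxError, ValueError):
    """The transient shows no variable fluorescence (FM <= F0)."""


class ConfigError(JipfluxError, ValueError):
    """A pipeline configuration is invalid or self-contradictory."""
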