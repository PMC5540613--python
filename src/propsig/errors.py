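"""Exception hierarchy shared across the pipeline stages."""


class PropsigError(Exception):
    """Base class for all package errors."""


class RecordingFormatError(PropsigError):
    """Malformed recording interchange file (missing/duplicate keys, bad samples)."""


class ValidationError(PropsigError):
    """A domain invariant is violated (timing, vocabulary, parameter range)."""


class CoverageError(PropsigError):
    """Recording too short to cover the requested analysis window."""


class LengthError(PropsigError):
    """Input sequence shorter than an operation's minimum length."""


class ConfigurationError(PropsigError):
    """Invalid configuration value or infeasible design specification."""


class DetectionError(PropsigError):
    """Event detection could not produce an onset estimate."""


class DelineationError(PropsigError):
    """Waveform delineation failed (e.g. no curve fit converged)."""
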