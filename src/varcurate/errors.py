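"""Exception types shared across the package."""


class VarcurateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VarcurateError):
    """An analysis-profile or CLI configuration problem."""


class ParseError(VarcurateError):
    """Malformed input data (VCF, coverage track, BED, metrics)."""


class StoreBusyError(VarcurateError):
    """The observation store is locked by a concurrent writer; retryable."""
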