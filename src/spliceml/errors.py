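"""Exception hierarchy shared across the package."""


class SpliceMLError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SpliceMLError):
    """Invalid or unparsable run configuration."""


class DataError(SpliceMLError):
    """Malformed or inconsistent input data."""


class NoEvidenceError(DataError):
    """A splice-site evidence record carries no reads at all."""


class InsufficientDataError(DataError):
    """A statistic is undefined because too few observations qualify."""
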