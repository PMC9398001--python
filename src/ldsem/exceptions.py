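"""Exception hierarchy.

``ConfigurationError`` marks problems a user can fix in a config file or
column mapping (CLI exit code 2); ``DataError`` marks problems with the data
itself (exit code 1).
"""


class LdsemError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LdsemError):
    """Invalid configuration, thresholds, or unresolvable column mapping."""


class DataError(LdsemError):
    """Invalid or inconsistent data (misaligned SNP sets, empty intersection,
    non-PSD covariance at a named SNP, ...)."""
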