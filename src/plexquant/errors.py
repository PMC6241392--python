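"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
FitError -> 4.
"""


class PlexquantError(Exception):
    """Base class for all package errors."""


class ConfigError(PlexquantError):
    """Invalid configuration, panel file, or CLI arguments."""


class DataError(PlexquantError):
    """Malformed or inconsistent event data (FCS dialect problems,
    missing channels, cluster-count mismatches, ...)."""


class FitError(PlexquantError):
    """Standard-curve fitting failed or did not converge."""
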