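"""Exception hierarchy shared across the pipeline.

The CLI maps ConfigError to exit code 2 and DataError to exit code 3.
"""


class EpidriverError(Exception):
    """Base class for all package errors."""


class ConfigError(EpidriverError):
    """Invalid or inconsistent run configuration."""


class DataError(EpidriverError):
    """Malformed or insufficient input data."""
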