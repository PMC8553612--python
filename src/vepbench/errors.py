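"""Exception hierarchy shared across the pipeline.

ConfigError maps to CLI exit code 1 (bad configuration / unloadable spec),
DataError to exit code 2 (malformed or inconsistent input data).
"""


class VepbenchError(Exception):
    """Base class for all package errors."""


class ConfigError(VepbenchError):
    """Invalid configuration, threshold spec, or simulation profile."""


class DataError(VepbenchError):
    """Malformed, inconsistent, or degenerate input data."""
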