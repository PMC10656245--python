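"""Shared exception types.

``ConfigError`` marks problems with parameters or configuration (CLI exit
code 2), ``DataError`` problems with the input data themselves (exit code 3).
"""


class ConfigError(ValueError):
    """Invalid or incomplete configuration / parameterization."""


class DataError(ValueError):
    """Invalid, inconsistent or missing input data."""
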