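"""Exception hierarchy.

``ConfigurationError`` maps to CLI exit code 2, ``DataError`` to 3.
"""


class BlastomicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BlastomicsError):
    """Invalid configuration; the message names the offending field."""


class DataError(BlastomicsError):
    """Input data violates a precondition of an analysis step."""
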