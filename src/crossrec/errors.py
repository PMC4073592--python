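"""Exception hierarchy.

ValidationError maps to CLI exit code 2 (bad parameters / configuration),
DataError to exit code 3 (unreadable or malformed input data).
"""


class CrossRecError(Exception):
    """Base class for all crossrec errors."""


class ValidationError(CrossRecError):
    """Invalid parameter values or parameter/data combinations."""


class InsufficientLengthError(ValidationError):
    """Series too short for the requested delay/dimension."""


class DataError(CrossRecError):
    """Malformed, missing, or inconsistent input data."""
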