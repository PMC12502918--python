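"""Exception types shared across the package."""


class SynclassError(Exception):
    """Base class for package errors."""


class InvalidBaseError(SynclassError, ValueError):
    """A sequence contained a character outside A/C/G/T where required."""


class InputError(SynclassError):
    """An input file was missing, empty or malformed."""


class ConfigurationError(SynclassError):
    """Inconsistent parameters or labels."""


class FormatError(SynclassError):
    """A serialized database was unreadable or corrupt."""
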