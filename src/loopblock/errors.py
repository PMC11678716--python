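"""Exception hierarchy shared across the package."""


class LoopblockError(Exception):
    """Base class for all package errors."""


class ValidationError(LoopblockError):
    """A record violates a structural invariant (e.g. start >= end)."""


class FormatError(LoopblockError):
    """A file could not be parsed; the message names the offending line."""


class ConfigurationError(LoopblockError):
    """A parameter or parameter combination is invalid."""


class DegenerateDataError(LoopblockError):
    """The input is structurally valid but the result is undefined
    (e.g. zero-variance correlation, empty sample)."""
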