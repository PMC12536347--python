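"""Exception types shared across the package."""


class CogloadError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(CogloadError, ValueError):
    """A function argument violates its documented precondition."""


class MissingChannelError(CogloadError, KeyError):
    """A required channel or export file is absent."""


class ParseError(CogloadError, ValueError):
    """A device export file could not be parsed; message names file and line."""


class LowConfidenceSyncError(CogloadError, RuntimeError):
    """Cross-correlation peak too weak to trust a synchronisation offset."""


class InsufficientBeatsError(CogloadError, RuntimeError):
    """Too few heartbeats detected to compute interval statistics."""
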