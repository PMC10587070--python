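"""Exception hierarchy."""


class CallCortexError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(CallCortexError, ValueError):
    """A configuration value violates its documented constraints."""


class ContractError(CallCortexError, ValueError):
    """An operation was called with inputs violating its preconditions."""


class EmptyInputError(ContractError):
    """An operation received an empty waveform / trial set it cannot use."""


class AlignmentError(CallCortexError, RuntimeError):
    """Audio and neural sync-pulse trains cannot be matched."""


class DegenerateInputError(CallCortexError, ValueError):
    """Zero-variance or otherwise degenerate data for a statistical test."""
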