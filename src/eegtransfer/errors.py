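"""Exception hierarchy shared across the pipeline."""


class EEGTransferError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EEGTransferError, ValueError):
    """An argument violates an operation's contract."""


class DegenerateInputError(EEGTransferError, ValueError):
    """Input is structurally valid but degenerate (e.g. a constant channel)."""
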