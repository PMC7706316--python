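"""Exception hierarchy shared across the package."""


class TasselgenError(Exception):
    """Base class for all package errors."""


class ParameterError(TasselgenError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(TasselgenError, ValueError):
    """Input lacks the structure an operation requires (e.g. a constant
    channel given to a histogram thresholder)."""


class ShapeError(TasselgenError, ValueError):
    """Array shapes are inconsistent with the operation's contract."""


class TrainingError(TasselgenError, RuntimeError):
    """Adversarial training aborted (e.g. a loss became non-finite)."""
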