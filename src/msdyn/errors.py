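"""Exception hierarchy shared across the package."""


class MsdError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MsdError):
    """An input file is malformed or missing required metadata (e.g. no sampling rate)."""


class ParameterError(MsdError, ValueError):
    """An argument violates a precondition (bad band edges, k out of range, ...)."""


class DimensionError(ParameterError):
    """Shapes or channel counts of two objects do not agree."""


class CapabilityError(MsdError):
    """The operation needs information the object does not carry (e.g. channel positions)."""


class UndefinedStatisticError(MsdError, ArithmeticError):
    """A statistic is undefined on this input (zero variance, all-zero GFP, ...)."""


class StageError(MsdError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
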