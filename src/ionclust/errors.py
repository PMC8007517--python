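"""Exception hierarchy shared across the package."""


class IonclustError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IonclustError):
    """A file or table does not conform to the expected layout."""


class ParameterError(IonclustError, ValueError):
    """A parameter value violates a documented precondition."""


class ValidationError(IonclustError, ValueError):
    """Input data violates a documented invariant (e.g. negative intensities)."""


class EmptySelectionError(IonclustError):
    """A query selected no data (e.g. no m/z axis entry within tolerance)."""


class UndefinedMetricError(IonclustError):
    """A metric is undefined for the given inputs (e.g. zero isotope pairs)."""


class CapabilityError(IonclustError):
    """An optional capability is unavailable in this installation."""


class StageError(IonclustError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
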