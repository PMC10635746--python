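"""Exception hierarchy shared across the pipeline stages."""


class MLDSTError(Exception):
    """Base class for all package errors."""


class ParameterError(MLDSTError, ValueError):
    """An argument violates a documented precondition."""


class ContractError(MLDSTError, ValueError):
    """Inputs to an operation violate its data contract."""


class EmptyROIError(MLDSTError):
    """No foreground survives binarization + erosion."""


class EncodingError(MLDSTError, ValueError):
    """Unknown class label, or a vector that is not one-hot."""


class TrainingError(MLDSTError):
    """Training cannot proceed (e.g. single-class training set)."""


class StateError(MLDSTError):
    """Operation called on an object in the wrong state (e.g. untrained model)."""


class ConfigurationError(MLDSTError, ValueError):
    """Invalid model or pipeline configuration."""


class TotalConflictError(MLDSTError):
    """Dempster's rule is undefined: the two sources are in total conflict (k = 1)."""

    def __init__(self, argmax1: str, argmax2: str):
        self.argmax1 = argmax1
        self.argmax2 = argmax2
        super().__init__(
            f"total conflict (k=1) between sources committed to "
            f"{argmax1!r} and {argmax2!r}"
        )
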