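"""Exception types shared across the package."""


class FGCNError(Exception):
    """Base class for package errors."""


class ParameterError(FGCNError, ValueError):
    """An argument is outside its documented domain."""


class EstimationError(FGCNError, RuntimeError):
    """A statistical estimate could not be computed from the data given."""


class DegenerateSignalError(EstimationError):
    """A signal has no usable variation (constant channel, zero residual)."""


class IsolatedNodeError(FGCNError, ValueError):
    """A graph node has zero degree and cannot be spectrally normalized."""
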