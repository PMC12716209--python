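"""Exception hierarchy shared across the pipeline."""


class LamscreenError(Exception):
    """Base class for all package errors."""


class ParameterError(LamscreenError, ValueError):
    """A simulation or analysis parameter is outside its valid domain."""


class CapacityError(LamscreenError, RuntimeError):
    """A request exceeds what the available data/geometry can supply."""


class DegenerateInputError(LamscreenError, ValueError):
    """Input carries no usable signal (e.g. a constant image)."""


class InsufficientControlError(LamscreenError, ValueError):
    """Too few control cells to fit thresholds or a control model."""


class InputError(LamscreenError, ValueError):
    """Malformed or inconsistent user input (missing channel, shape mismatch)."""


class ConfigurationError(LamscreenError, ValueError):
    """Required run configuration is missing (e.g. no control condition)."""
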