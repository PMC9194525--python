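"""Exception hierarchy shared across the package."""


class FilterscopeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FilterscopeError, ValueError):
    """Invalid generator, model, or experiment configuration."""


class ShapeError(FilterscopeError, ValueError):
    """Tensor shape incompatible with a layer or operation."""


class ZeroVarianceError(FilterscopeError, ValueError):
    """A subject's concatenated signal has no variance and cannot be z-scored."""


class RestorationError(FilterscopeError, RuntimeError):
    """Model weights were not restored bit-exactly after a perturbation run."""


class PropagationError(FilterscopeError, ValueError):
    """A layer has no registered relevance-propagation rule."""
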