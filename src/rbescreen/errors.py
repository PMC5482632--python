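"""Exception types shared across the package."""


class RBEScreenError(Exception):
    """Base class for package errors."""


class ConfigurationError(RBEScreenError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class DataError(RBEScreenError, ValueError):
    """An input table violates the documented format."""


class ConvergenceError(RBEScreenError, RuntimeError):
    """An iterative fit failed to converge (e.g. monotone partial likelihood)."""
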