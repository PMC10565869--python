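"""Exception hierarchy shared across the toolkit.

``ValidationError`` covers malformed arguments and configuration; the
``NumericalError`` family covers runtime failures of the numerical
procedures.  The CLI maps these to exit codes 2 and 3 respectively.
"""


class BoneccError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(BoneccError, ValueError):
    """Invalid argument, configuration value or file content."""


class NumericalError(BoneccError, RuntimeError):
    """A numerical procedure failed to produce a usable result."""


class SingularInversionError(NumericalError):
    """Regularized inversion hit an exactly singular spectrum."""


class DivergenceError(NumericalError):
    """An adaptive-filter run diverged (the step size is the usual suspect)."""


class NonConvergenceError(NumericalError):
    """An iterative procedure hit its trial/iteration cap without finishing."""
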