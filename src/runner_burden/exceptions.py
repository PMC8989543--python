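"""Exception and warning types used across the package."""


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class SupportError(ValueError):
    """A count lies outside the support of the truncated distribution."""


class NumericalError(ArithmeticError):
    """A computation lost all precision (e.g. truncation mass ~ 1)."""


class IdentifiabilityError(ValueError):
    """The design matrix does not identify the regression coefficients."""


class SchemaError(ValueError):
    """An input table does not match its documented schema."""


class BackgroundShrinkageError(RuntimeError):
    """The recursive background purification removed too many genes."""


class ConvergenceWarning(UserWarning):
    """The optimizer stopped without meeting the gradient criterion."""
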