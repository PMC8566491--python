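"""Exception hierarchy shared by all oralflow modules."""


class OralflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(OralflowError, ValueError):
    """An argument violates a documented precondition."""


class NumericalError(OralflowError, RuntimeError):
    """A numerical routine failed (solver breakdown, out-of-regime input)."""


class FittingError(OralflowError, RuntimeError):
    """A model fit did not converge from any starting point."""
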