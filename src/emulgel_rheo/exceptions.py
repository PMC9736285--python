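"""Exception and warning types shared across the package.

The CLI maps :class:`ValidationError` to exit code 2 and
:class:`ModelDomainError` to exit code 3.
"""


class EmulgelRheoError(Exception):
    """Base class for all package errors."""


class ValidationError(EmulgelRheoError, ValueError):
    """Invalid user input: bad values, malformed tables, broken invariants."""


class ModelDomainError(EmulgelRheoError, ValueError):
    """Inputs outside the mathematical domain of a model equation
    (vanishing denominators, no detectable plateau, D >= 3, ...)."""


class NonPhysicalResultWarning(UserWarning):
    """A computed quantity is outside its physical range (e.g. a negative
    relative modulus, or a fractal dimension outside (0, 3)).  The value is
    still returned so callers can inspect and report it."""
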