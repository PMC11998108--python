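"""Exception hierarchy for mnswell.

All user-facing errors derive from :class:`MnswellError` so callers can
catch the package's failures in one clause; validation errors additionally
derive from :class:`ValueError` so plain-Python callers behave as expected.
"""


class MnswellError(Exception):
    """Base class for all mnswell errors."""


class ValidationError(MnswellError, ValueError):
    """An input violates a documented precondition or type invariant."""


class RangeError(MnswellError, ValueError):
    """A requested interval lies outside the support of a profile/series."""


class FitError(MnswellError):
    """Base class for model-fitting failures."""


class InsufficientDataError(FitError):
    """Too few usable points to fit the requested model."""


class DegenerateFitError(FitError):
    """The fitted line is inconsistent with the kinetic model.

    Raised when the linearised regression returns a nonpositive slope or
    intercept, e.g. for a constant swelling series (line through the
    origin) or a series already at plateau.
    """


class TransportDomainError(MnswellError, ValueError):
    """Concentration at or beyond the two-compartment equilibrium bound.

    The permeability inversion takes ``log(1 - 2*Ct/C0)``; at ``Ct >= C0/2``
    the argument is nonpositive, signalling either equilibrium reached or a
    measurement error.
    """
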