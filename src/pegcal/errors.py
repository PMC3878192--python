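"""Exception hierarchy for pegcal.

All errors raised deliberately by the package derive from :class:`PegcalError`
so callers can catch the package's failures with a single except clause.
"""


class PegcalError(Exception):
    """Base class for all pegcal errors."""


class DomainError(PegcalError, ValueError):
    """An input lies outside the physical domain of an operation
    (negative length, zero volume, non-positive molar mass, ...)."""


class FitError(PegcalError, ValueError):
    """A regression cannot be performed (too few points, degenerate design,
    non-positive values where a log is required)."""


class FormatError(PegcalError, ValueError):
    """A file does not parse as the expected tabular format."""


class WavelengthRangeError(PegcalError, ValueError):
    """A wavelength query falls outside a spectrum's measured grid."""


class DegenerateDenominatorError(PegcalError, ArithmeticError):
    """The blank-corrected aggregate-band absorbance is at or below the
    numerical floor: the sample is fully stable and its stability degree
    lies above the assay's dynamic range."""


class UnscreenedModelError(PegcalError, NotImplementedError):
    """The unscreened (finite electrostatic) interaction mode was requested;
    only the fully salt-screened regime is modelled."""
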