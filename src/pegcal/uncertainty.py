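"""A minimal value-with-uncertainty container.

Uncertainties are carried as one standard deviation and propagated to first
order (delta method) by the functions that consume them.  This mirrors the
mean ± sd reporting convention of triplicate bench measurements; it is not a
general error-propagation engine.
"""
from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class Measurement:
    """A scalar measurement with a one-sigma uncertainty.

    Parameters
    ----------
    value : float
        Central value.
    sd : float, optional
        One standard deviation. Must be non-negative; defaults to 0 (an
        exact value).
    """

    value: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"measurement value must be finite, got {self.value}")
        if not (self.sd >= 0.0):
            raise ValueError(f"measurement sd must be >= 0, got {self.sd}")

    def scaled(self, factor: float) -> "Measurement":
        """Return the measurement multiplied by an exact constant."""
        return Measurement(self.value * factor, self.sd * abs(factor))

    def relative_sd(self) -> float:
        """sd / |value|; raises for a zero central value."""
        if self.value == 0.0:
            raise ZeroDivisionError("relative sd undefined for zero value")
        return self.sd / abs(self.value)

    def __iter__(self):
        yield self.value
        yield self.sd


def as_measurement(x: "Measurement | float | int") -> Measurement:
    """Coerce a bare number (treated as exact) or pass through a Measurement."""
    if isinstance(x, Measurement):
        return x
    return Measurement(float(x), 0.0)
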