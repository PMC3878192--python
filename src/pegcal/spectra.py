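"""UV–vis spectrum handling and the stability-degree statistic.

A gold sol's plasmon band sits near 520 nm while aggregated particles
absorb at longer wavelengths, so the ratio of the stable-peak absorbance to
the blank-corrected aggregate-peak absorbance quantifies how much of the
population survived a salt challenge:

    SD = A(lambda_stable) / [A(lambda_agg) - A_blank(lambda_agg)]

where the blank is the same sol diluted with water instead of salt (its
aggregate-wavelength absorbance is the tail of the stable band).  The
subtraction is applied in the denominator only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDenominatorError,
    DomainError,
    FormatError,
    WavelengthRangeError,
)
from .solution_chemistry import InstrumentProfile
from .uncertainty import Measurement

#: Denominator floor (AU) below which a stability degree is ruled
#: above the assay's dynamic range rather than divided out.
DENOMINATOR_FLOOR = 1e-6


@dataclass(frozen=True)
class Spectrum:
    """One absorbance spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray  # nm
    absorbances: np.ndarray  # AU
    sample_id: str = ""
    replicate: int = 0
    is_blank: bool = False

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        if wl.ndim != 1 or wl.shape != ab.shape:
            raise FormatError("wavelengths and absorbances must be equal-length 1-D")
        if wl.size < 2:
            raise FormatError("a spectrum needs at least 2 points")
        if not (np.isfinite(wl).all() and np.isfinite(ab).all()):
            raise FormatError("spectrum contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            order = np.argsort(wl, kind="stable")
            wl, ab = wl[order], ab[order]
            if np.any(np.diff(wl) <= 0):
                raise FormatError("wavelength grid contains duplicates")
            warnings.warn(
                f"spectrum {self.sample_id!r}: wavelength grid was not sorted; sorting",
                stacklevel=2,
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass(frozen=True)
class StabilityDegree:
    """The SD statistic with the absorbances that produced it."""

    value: float
    stable_abs: float
    aggregate_abs: float
    blank_aggregate_abs: float
    profile_id: str = ""

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise DomainError("stability degree must be > 0")
        if not (self.aggregate_abs > self.blank_aggregate_abs):
            raise DomainError("aggregate absorbance must exceed the blank's")


def read_spectrum(
    path: "str | Path",
    sample_id: str = "",
    replicate: int = 0,
    is_blank: bool = False,
) -> Spectrum:
    """Read a two-column wavelength/absorbance CSV (header optional)."""
    path = Path(path)
    try:
        head = pd.read_csv(path, nrows=1, header=None)
    except Exception as exc:  # empty file, parse failure
        raise FormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    try:
        float(head.iloc[0, 0])
        header = None
    except (TypeError, ValueError):
        header = 0
    try:
        df = pd.read_csv(path, header=header, usecols=[0, 1], float_precision="round_trip")
        wl = df.iloc[:, 0].astype(float).to_numpy()
        ab = df.iloc[:, 1].astype(float).to_numpy()
    except (ValueError, TypeError, IndexError) as exc:
        raise FormatError(f"{path}: non-numeric or malformed rows") from exc
    if not sample_id:
        sample_id = path.stem
    return Spectrum(wl, ab, sample_id=sample_id, replicate=replicate, is_blank=is_blank)


def write_spectrum(spectrum: Spectrum, path: "str | Path") -> None:
    """Write the standard two-column CSV (wavelength_nm, absorbance)."""
    df = pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "absorbance": spectrum.absorbances}
    )
    # %.17g keeps the round trip bit-exact for float64
    df.to_csv(path, index=False, float_format="%.17g")


def absorbance_at(spectrum: Spectrum, wavelength: float) -> float:
    """Linearly interpolated absorbance; exact on grid points."""
    wl = spectrum.wavelengths
    if not (wl[0] <= wavelength <= wl[-1]):
        raise WavelengthRangeError(
            f"{wavelength} nm outside measured range [{wl[0]}, {wl[-1]}] nm"
        )
    return float(np.interp(wavelength, wl, spectrum.absorbances))


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale so the maximum absorbance is 1 (shape-preserving)."""
    peak = float(spectrum.absorbances.max())
    if peak <= 0:
        raise DomainError("cannot normalize a spectrum with no positive absorbance")
    return replace(spectrum, absorbances=spectrum.absorbances / peak)


def stability_degree(
    sample: Spectrum,
    blank: Spectrum,
    profile: InstrumentProfile,
    floor: float = DENOMINATOR_FLOOR,
) -> StabilityDegree:
    """Compute SD for one replicate against the diluted no-salt blank.

    Raises DegenerateDenominatorError when the blank-corrected aggregate
    absorbance is at or below ``floor`` — the sample is then
    indistinguishable from a fully stable sol and its SD is above range.
    """
    a_stable = absorbance_at(sample, profile.stable_wavelength_nm)
    a_agg = absorbance_at(sample, profile.aggregate_wavelength_nm)
    a_agg_blank = absorbance_at(blank, profile.aggregate_wavelength_nm)
    denom = a_agg - a_agg_blank
    if denom <= floor:
        raise DegenerateDenominatorError(
            f"blank-corrected aggregate absorbance {denom:.3g} AU <= floor "
            f"{floor:g}: stability degree above assay range"
        )
    return StabilityDegree(
        value=a_stable / denom,
        stable_abs=a_stable,
        aggregate_abs=a_agg,
        blank_aggregate_abs=a_agg_blank,
        profile_id=profile.profile_id,
    )


def replicate_stability(
    samples: Sequence[Spectrum],
    blank: Spectrum,
    profile: InstrumentProfile,
    floor: float = DENOMINATOR_FLOOR,
) -> tuple[Measurement, list[float], int]:
    """Per-replicate SDs summarised as mean ± sample sd.

    Returns (summary, per-replicate values, number of above-range
    replicates).  With a single usable replicate the sd is reported as 0
    (no replicate scatter is observable).  Raises
    DegenerateDenominatorError when every replicate is above range.
    """
    values: list[float] = []
    n_degenerate = 0
    for spec in samples:
        try:
            values.append(stability_degree(spec, blank, profile, floor=floor).value)
        except DegenerateDenominatorError:
            n_degenerate += 1
    if not values:
        raise DegenerateDenominatorError(
            "all replicates above assay range (fully stable sample)"
        )
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else 0.0
    return Measurement(float(arr.mean()), sd), values, n_degenerate
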