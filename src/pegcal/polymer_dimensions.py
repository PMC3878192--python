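"""Ideal-chain size conversions and the size–molar-mass power law for PEG.

For a flexible linear polymer near theta conditions the three standard size
measures are related by constants: the hydrodynamic radius measured by DLS
satisfies Rh = 0.85·Rg, and the root-mean-square end-to-end length of an
ideal chain is ⟨h²⟩^1/2 = √6·Rg.  Across a homologous series the chain size
scales as a power of molar mass, ⟨h²⟩^1/2 = a·Mw^ν with ν → 0.5 for an
ideal (Gaussian) chain; fitting that law on reference samples and inverting
it converts a size estimate into a molar-mass estimate.

Lengths are in nm and molar masses in Da throughout.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, FitError
from .uncertainty import Measurement, as_measurement

#: DLS-to-gyration ratio for flexible coils: Rh = 0.85 * Rg.
RH_OVER_RG = 0.85

#: End-to-end over gyration ratio for an ideal chain: h_rms = sqrt(6) * Rg.
SQRT6 = math.sqrt(6.0)


@dataclass(frozen=True)
class PowerLawModel:
    """Size–mass scaling law h_rms = prefactor * Mw**exponent.

    prefactor is in nm·Da^(−exponent); exponent is the scaling coefficient ν
    (0.5 for an ideal chain, 0.588 for a good-solvent coil).  r_squared is
    the coefficient of determination of the (possibly weighted) log-space
    fit that produced the model.
    """

    prefactor: float
    exponent: float
    r_squared: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (self.prefactor > 0):
            raise DomainError(f"prefactor must be > 0, got {self.prefactor}")
        if not (0.0 < self.exponent < 1.0):
            raise DomainError(f"exponent must be in (0, 1), got {self.exponent}")
        if math.isfinite(self.r_squared) and not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise DomainError(f"r_squared must be in [0, 1], got {self.r_squared}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PowerLawModel":
        d = json.loads(text)
        return cls(
            prefactor=float(d["prefactor"]),
            exponent=float(d["exponent"]),
            r_squared=float(d.get("r_squared", float("nan"))),
            n_points=int(d.get("n_points", 0)),
        )


@dataclass(frozen=True)
class PolymerSample:
    """One reference PEG sample: molar mass plus the three size measures.

    rg and h_rms are normally derived from rh via the ideal-chain constants;
    use :meth:`from_dls` to build a sample from a DLS measurement.
    """

    label: str
    mw: Measurement
    rh: Measurement
    rg: Measurement
    h_rms: Measurement
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not (self.mw.value > 0):
            raise DomainError(f"{self.label}: molar mass must be > 0")
        if not (self.rh.value > 0):
            raise DomainError(f"{self.label}: hydrodynamic radius must be > 0")
        # derived columns must be consistent with the conversion constants
        if not math.isclose(self.rg.value, self.rh.value / RH_OVER_RG, rel_tol=5e-3):
            raise DomainError(f"{self.label}: rg inconsistent with rh/0.85")
        if not math.isclose(self.h_rms.value, SQRT6 * self.rg.value, rel_tol=5e-3):
            raise DomainError(f"{self.label}: h_rms inconsistent with sqrt(6)*rg")

    @classmethod
    def from_dls(
        cls,
        label: str,
        mw: "Measurement | float",
        rh: "Measurement | float",
        n_replicates: int = 3,
    ) -> "PolymerSample":
        mw = as_measurement(mw)
        rh = as_measurement(rh)
        rg = rh_to_rg(rh)
        return cls(label, mw, rh, rg, rg_to_h_rms(rg), n_replicates)


def rh_to_rg(rh: "Measurement | float") -> Measurement:
    """Convert a hydrodynamic radius to a radius of gyration (Rg = Rh/0.85)."""
    rh = as_measurement(rh)
    if rh.value < 0:
        raise DomainError(f"hydrodynamic radius must be >= 0, got {rh.value}")
    return rh.scaled(1.0 / RH_OVER_RG)


def rg_to_h_rms(rg: "Measurement | float") -> Measurement:
    """Convert a radius of gyration to the RMS end-to-end length (√6·Rg)."""
    rg = as_measurement(rg)
    if rg.value < 0:
        raise DomainError(f"radius of gyration must be >= 0, got {rg.value}")
    return rg.scaled(SQRT6)


def rh_to_h_rms(rh: "Measurement | float") -> Measurement:
    """Hydrodynamic radius straight to RMS end-to-end length (√6/0.85 scale)."""
    return rg_to_h_rms(rh_to_rg(rh))


def fit_power_law(
    samples: Sequence[PolymerSample],
    *,
    space: str = "log",
    weighted: "bool | None" = None,
) -> PowerLawModel:
    """Fit h_rms = a·Mw^ν on a reference panel.

    The default is linear least squares in log–log space.  When every sample
    carries a positive h_rms uncertainty (and ``weighted`` is not explicitly
    False) the log-space fit is weighted by 1/σ² with σ = h_sd/h, the
    instrumental weighting a spreadsheet fit against error bars applies;
    equal uncertainties reduce to the unweighted fit.  ``space="linear"``
    instead minimises residuals of h itself (nonlinear least squares).

    Raises FitError for fewer than 3 usable points or non-positive data.
    """
    if len(samples) < 3:
        raise FitError(f"power-law fit needs >= 3 samples, got {len(samples)}")
    mw = np.array([s.mw.value for s in samples], dtype=float)
    h = np.array([s.h_rms.value for s in samples], dtype=float)
    hsd = np.array([s.h_rms.sd for s in samples], dtype=float)
    if np.any(mw <= 0) or np.any(h <= 0):
        raise FitError("power-law fit requires strictly positive Mw and h_rms")

    if weighted is None:
        weighted = bool(np.all(hsd > 0))
    elif weighted and not np.all(hsd > 0):
        raise FitError("weighted fit requested but some h_rms sds are zero")

    if space == "linear":
        sigma = hsd if weighted else None
        popt, _ = optimize.curve_fit(
            lambda m, a, b: a * m**b, mw, h, p0=(0.1, 0.5), sigma=sigma, maxfev=20000
        )
        resid = h - popt[0] * mw ** popt[1]
        r2 = 1.0 - float(np.sum(resid**2) / np.sum((h - h.mean()) ** 2))
        return PowerLawModel(float(popt[0]), float(popt[1]), r2, len(samples))
    if space != "log":
        raise ValueError(f"space must be 'log' or 'linear', got {space!r}")

    x = np.log(mw)
    y = np.log(h)
    if weighted:
        w = (h / hsd) ** 2  # 1/sigma_log^2 with sigma_log ~ h_sd/h
        wsum = w.sum()
        xbar = np.sum(w * x) / wsum
        ybar = np.sum(w * y) / wsum
        sxx = np.sum(w * (x - xbar) ** 2)
        if sxx <= 0:
            raise FitError("degenerate design: all Mw identical")
        slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
        intercept = float(ybar - slope * xbar)
        yhat = intercept + slope * x
        r2 = 1.0 - float(np.sum(w * (y - yhat) ** 2) / np.sum(w * (y - ybar) ** 2))
    else:
        if np.allclose(x, x[0]):
            raise FitError("degenerate design: all Mw identical")
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    return PowerLawModel(math.exp(intercept), slope, r2, len(samples))


def mw_to_h_rms(mw: float, model: PowerLawModel) -> float:
    """Forward evaluation of the scaling law: h = a·Mw^ν (nm)."""
    if mw <= 0:
        raise DomainError(f"molar mass must be > 0, got {mw}")
    return model.prefactor * mw**model.exponent


def h_rms_to_mw(h_rms: "Measurement | float", model: PowerLawModel) -> Measurement:
    """Invert the scaling law: Mw = (h/a)^(1/ν), uncertainty to first order.

    dMw/dh = Mw/(ν·h), so sd_Mw = Mw · sd_h / (ν·h).
    """
    h = as_measurement(h_rms)
    if h.value <= 0:
        raise DomainError(f"h_rms must be > 0, got {h.value}")
    mw = (h.value / model.prefactor) ** (1.0 / model.exponent)
    sd = mw * h.sd / (model.exponent * h.value)
    return Measurement(mw, sd)
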