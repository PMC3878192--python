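"""Solution-side arithmetic for the salt-challenge aggregation assay.

Covers the bookkeeping around the bench protocol: NaCl molarity after
spiking a sample with stock solution, the Debye screening length it
produces, nanoparticle molar/number concentration from a Beer–Lambert read,
the total particle surface area available for polymer adsorption, and a
check that the bulk polymer concentration saturates that surface.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

from .errors import DomainError

AVOGADRO = 6.02214e23  # 1/mol
NACL_MOLAR_MASS = 58.44  # g/mol
# Debye length prefactor for a symmetric electrolyte in water at 25 C:
# kappa^-1 = 0.3041 / (z * sqrt(C)) nm with C in mol/L.
DEBYE_PREFACTOR_NM = 0.3041


@dataclass(frozen=True)
class SolutionConditions:
    """Electrolyte conditions of the assay buffer."""

    electrolyte_molarity: float  # mol/L
    valence: int = 1
    temperature: float = 298.15  # K
    ph: float = 7.0

    def __post_init__(self) -> None:
        if self.electrolyte_molarity < 0:
            raise DomainError("electrolyte molarity must be >= 0")
        if self.valence < 1:
            raise DomainError("electrolyte valence must be >= 1")


@dataclass(frozen=True)
class InstrumentProfile:
    """Optical constants of one nanoparticle batch on one spectrophotometer.

    extinction_coefficient is the molar extinction at the stable-particle
    plasmon peak (cm^-1 M^-1); stable/aggregate wavelengths are the two
    fixed read positions of the assay.
    """

    profile_id: str
    particle_diameter_nm: float
    stable_wavelength_nm: float
    aggregate_wavelength_nm: float
    extinction_coefficient: float
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.particle_diameter_nm > 0):
            raise DomainError("particle diameter must be > 0")
        if self.stable_wavelength_nm == self.aggregate_wavelength_nm:
            raise DomainError("stable and aggregate wavelengths must differ")
        if not (self.extinction_coefficient > 0):
            raise DomainError("extinction coefficient must be > 0")
        if not (self.path_length_cm > 0):
            raise DomainError("path length must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "InstrumentProfile":
        return cls(**json.loads(text))


def spike_molarity(
    spike_volume_ul: float,
    stock_mass_fraction: float,
    sample_volume_ml: float,
    molar_mass: float = NACL_MOLAR_MASS,
) -> float:
    """Final salt molarity (mol/L) after spiking a sample with stock.

    stock_mass_fraction is the w/v strength in g per 100 mL.  Volumes are
    treated as additive.  A zero spike returns 0.
    """
    if spike_volume_ul < 0 or sample_volume_ml <= 0:
        raise DomainError("volumes must be positive (spike may be zero)")
    if stock_mass_fraction <= 0 or molar_mass <= 0:
        raise DomainError("stock strength and molar mass must be > 0")
    spike_ml = spike_volume_ul * 1e-3
    grams = spike_ml * stock_mass_fraction / 100.0
    total_l = (sample_volume_ml + spike_ml) * 1e-3
    if total_l <= 0:
        raise DomainError("total volume must be > 0")
    return grams / molar_mass / total_l


def debye_length(conditions: "SolutionConditions | float", valence: int = 1) -> float:
    """Debye screening length kappa^-1 in nm.

    Accepts a SolutionConditions or a bare molarity plus valence.  Valid for
    a single symmetric electrolyte in water at 25 C.  Zero molarity is an
    error (the screening length would be infinite).
    """
    if isinstance(conditions, SolutionConditions):
        c, z = conditions.electrolyte_molarity, conditions.valence
    else:
        c, z = float(conditions), valence
    if c <= 0:
        raise DomainError("molarity must be > 0 for a finite screening length")
    if z < 1:
        raise DomainError("valence must be >= 1")
    return DEBYE_PREFACTOR_NM / (z * math.sqrt(c))


def molarity_from_absorbance(absorbance: float, profile: InstrumentProfile) -> float:
    """Beer–Lambert particle molarity: A / (epsilon * path) in mol/L."""
    if absorbance < 0:
        raise DomainError("absorbance must be >= 0")
    return absorbance / (profile.extinction_coefficient * profile.path_length_cm)


def number_density(molarity: float) -> float:
    """Particles per mL from molar concentration."""
    if molarity < 0:
        raise DomainError("molarity must be >= 0")
    return molarity * AVOGADRO / 1000.0


def total_surface_area(density_per_ml: float, diameter_nm: float) -> float:
    """Total sphere surface area in m^2 per mL of suspension."""
    if density_per_ml < 0:
        raise DomainError("number density must be >= 0")
    if diameter_nm <= 0:
        raise DomainError("diameter must be > 0")
    area_nm2 = math.pi * diameter_nm**2
    return density_per_ml * area_nm2 * 1e-18


def saturation_excess(
    bulk_conc_mg_ml: float, mw_da: float, rh_nm: float, area_m2_ml: float
) -> float:
    """log10 of the polymer excess over a monolayer requirement.

    Molecules available per mL (from the bulk concentration) divided by
    molecules needed to tile the particle surface with one molecule per
    pi*Rh^2 footprint; returned on a log10 scale so "orders of magnitude
    excess" reads off directly.
    """
    if bulk_conc_mg_ml <= 0 or mw_da <= 0 or rh_nm <= 0 or area_m2_ml <= 0:
        raise DomainError("all saturation inputs must be > 0")
    available = bulk_conc_mg_ml * 1e-3 / mw_da * AVOGADRO
    footprint_m2 = math.pi * rh_nm**2 * 1e-18
    if footprint_m2 <= 0:
        raise DomainError("zero molecular footprint")
    needed = area_m2_ml / footprint_m2
    return math.log10(available / needed)
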