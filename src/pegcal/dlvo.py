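"""Pair-interaction energies for polymer-coated nanoparticles (DLVO).

In the fully salt-screened regime the electrostatic term vanishes and the
total pair energy is the sum of a steric repulsion from the adsorbed
polymer layers and a van der Waals attraction between the metal cores:

    U_total(L) = U_steric(L) + U_vdW(L),        U_elec = 0.

The steric term, for two spheres of core radius R carrying adlayers of
thickness t, is U0 * B(y) on 2R <= L < 2R + 2t with y = (L - 2R)/(2t),

    B(y) = -ln y - (9/5)(1 - y) + (1/3)(1 - y)^3 - (1/30)(1 - y)^6,
    U0   = (pi^3 / 12) * sigma_p * N_p * l^2 * (R / t) * kB*T,

zero once the layers separate (y >= 1), and a +inf sentinel for core
overlap.  Note that B is not monotone: it diverges as y -> 0+ but carries a
shallow negative lobe (depth 0.18806*U0 at y = 0.6070) before reaching
B(1) = 0, so the onset of layer contact is weakly attractive in this model.
The van der Waals term is the sphere–sphere Derjaguin form
U_vdW = -A* R / (12 H) with H = L - 2R the surface separation.

Because -1/H beats the logarithmic steric divergence at contact, the global
minimum at H -> 0 (the primary minimum) is unbounded in the continuum
model.  Stability is therefore judged on the *secondary* minimum — the
outermost local minimum of the curve — whose depth shrinks as the adlayer
thickens.  Energies are reported in units of kB*T; the Hamaker constant is
supplied in joules.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import DomainError, UnscreenedModelError

BOLTZMANN = 1.380649e-23  # J/K

#: Location (y) and value of the negative lobe of the steric bracket.
BRACKET_LOBE_Y = 0.60701
BRACKET_LOBE_VALUE = -0.18806


@dataclass(frozen=True)
class DLVOParams:
    """Physical parameters of the coated-particle pair model.

    particle_radius_nm : core (TEM) radius R, nm
    adlayer_thickness_nm : adsorbed-polymer layer thickness t, nm
    graft_density_per_nm2 : surface density of adsorbed chains sigma_p
    segment_count : segments per chain N_p
    segment_length_nm : segment length l, nm
    temperature_k : absolute temperature
    hamaker_effective_j : effective Hamaker constant A* of the coated
        particles, J (a free parameter of the model)
    """

    particle_radius_nm: float
    adlayer_thickness_nm: float
    graft_density_per_nm2: float
    segment_count: float
    segment_length_nm: float
    hamaker_effective_j: float
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        for name in (
            "particle_radius_nm",
            "adlayer_thickness_nm",
            "graft_density_per_nm2",
            "segment_count",
            "segment_length_nm",
            "hamaker_effective_j",
            "temperature_k",
        ):
            if not (getattr(self, name) > 0):
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.adlayer_thickness_nm >= 10 * self.particle_radius_nm:
            raise DomainError("adlayer thickness implausibly large vs core radius")

    @property
    def kbt_joule(self) -> float:
        return BOLTZMANN * self.temperature_k


@dataclass(frozen=True)
class PotentialCurve:
    """A sampled total-energy curve with its secondary-minimum summary.

    separations are center-to-center distances L (nm); energies are in
    kB*T.  minimum_depth/minimum_location describe the outermost local
    minimum; both are None when the curve has no negative local minimum.
    """

    separations: np.ndarray
    energies: np.ndarray
    minimum_depth: Optional[float]
    minimum_location: Optional[float]

    @property
    def has_minimum(self) -> bool:
        return self.minimum_depth is not None


def steric_bracket(y: float) -> float:
    """The dimensionless steric profile B(y); requires 0 < y."""
    if y <= 0:
        raise DomainError(f"y must be > 0, got {y}")
    if y >= 1:
        return 0.0
    u = 1.0 - y
    return -math.log(y) - 1.8 * u + u**3 / 3.0 - u**6 / 30.0


def steric_amplitude(params: DLVOParams) -> float:
    """U0 in kB*T units: (pi^3/12) sigma_p N_p l^2 R / t."""
    return (
        math.pi**3
        / 12.0
        * params.graft_density_per_nm2
        * params.segment_count
        * params.segment_length_nm**2
        * params.particle_radius_nm
        / params.adlayer_thickness_nm
    )


def steric_potential(L: float, params: DLVOParams) -> float:
    """Steric repulsion at center-to-center distance L (kB*T).

    +inf sentinel for core overlap (L < 2R, including the y -> 0 logarithmic
    divergence at contact); zero once the adlayers no longer overlap
    (L >= 2R + 2t).
    """
    if L <= 0:
        raise DomainError(f"separation must be > 0, got {L}")
    two_r = 2.0 * params.particle_radius_nm
    if L <= two_r:
        return math.inf
    y = (L - two_r) / (2.0 * params.adlayer_thickness_nm)
    if y >= 1.0:
        return 0.0
    return steric_amplitude(params) * steric_bracket(y)


def vdw_potential(H: float, params: DLVOParams) -> float:
    """van der Waals attraction at surface separation H (kB*T)."""
    if H <= 0:
        raise DomainError(f"surface separation must be > 0, got {H}")
    energy_j = -params.hamaker_effective_j * params.particle_radius_nm / (12.0 * H)
    return energy_j / params.kbt_joule


def total_potential(L: float, params: DLVOParams, screened: bool = True) -> float:
    """Total pair energy at center-to-center distance L (kB*T).

    Only the salt-screened regime (U_elec = 0) is modelled; requesting the
    unscreened mode raises UnscreenedModelError.
    """
    if not screened:
        raise UnscreenedModelError(
            "only the fully screened (U_elec = 0) regime is implemented"
        )
    two_r = 2.0 * params.particle_radius_nm
    if L <= two_r:
        return math.inf
    return steric_potential(L, params) + vdw_potential(L - two_r, params)


def potential_curve(
    params: DLVOParams,
    n_points: int = 2000,
    h_max: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample U_total on an even surface-separation grid H in (0, h_max].

    h_max defaults to 6t.  Returns (L, U) arrays with L = 2R + H.
    """
    if n_points < 10:
        raise DomainError("need at least 10 grid points")
    if h_max is None:
        h_max = 6.0 * params.adlayer_thickness_nm
    if h_max <= 0:
        raise DomainError("h_max must be > 0")
    H = np.linspace(h_max / n_points, h_max, n_points)
    two_r = 2.0 * params.particle_radius_nm
    U = np.array([total_potential(two_r + h, params) for h in H])
    return two_r + H, U


def find_minimum(
    params: DLVOParams,
    n_points: int = 2000,
    h_max: Optional[float] = None,
) -> PotentialCurve:
    """Locate the secondary minimum of the total-energy curve.

    Scans H in (0, 6t] (or h_max), takes the outermost strictly negative
    local minimum, and polishes it with a bounded scalar minimisation.
    Curves with no negative local minimum (e.g. vanishing attraction in the
    sampled window) are returned with the minimum flagged absent.
    """
    L, U = potential_curve(params, n_points=n_points, h_max=h_max)
    finite = np.isfinite(U)
    if not finite.any():
        raise DomainError("no finite energies on the evaluation grid")

    idx = None
    for i in range(len(U) - 2, 0, -1):
        if not (finite[i] and finite[i - 1] and finite[i + 1]):
            continue
        if U[i] < 0 and U[i] <= U[i - 1] and U[i] <= U[i + 1]:
            idx = i
            break
    if idx is None:
        return PotentialCurve(L, U, None, None)

    res = optimize.minimize_scalar(
        lambda x: total_potential(x, params),
        bounds=(L[idx - 1], L[idx + 1]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    loc = float(res.x) if res.fun <= U[idx] else float(L[idx])
    depth = float(min(res.fun, U[idx]))
    return PotentialCurve(L, U, depth, loc)


def classify_stability(curve: PotentialCurve, threshold: float = 3.0) -> str:
    """"stable" or "aggregating" by secondary-minimum depth.

    A dispersion is called aggregating when the well is deeper than
    ``threshold`` kB*T (default 3, the order of thermal energy; override to
    taste — the choice of threshold is a convention, not a measurement).
    """
    if threshold <= 0:
        raise DomainError("threshold must be > 0")
    if not curve.has_minimum:
        return "stable"
    return "aggregating" if abs(curve.minimum_depth) > threshold else "stable"


def thickness_sweep(
    base: DLVOParams, thicknesses: Sequence[float], threshold: float = 3.0
) -> list[dict]:
    """Evaluate the secondary minimum across adlayer thicknesses.

    Returns one record per thickness with the depth, location and
    stability verdict; used by the CLI sweep and the sweep property tests.
    """
    from dataclasses import replace

    out = []
    for t in thicknesses:
        p = replace(base, adlayer_thickness_nm=float(t))
        curve = find_minimum(p)
        out.append(
            {
                "adlayer_thickness_nm": float(t),
                "minimum_depth_kbt": curve.minimum_depth,
                "minimum_location_nm": curve.minimum_location,
                "classification": classify_stability(curve, threshold),
            }
        )
    return out
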