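"""Synthetic two-band spectra, DLS replicates and calibration bundles.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised without an instrument:

* a chain of known molar mass has true size h = 0.0718·Mw^0.525 (the
  reference scaling law) and hydrodynamic radius Rh = 0.85·h/√6;
* thicker adlayers stabilise the particles, so the aggregated fraction f
  falls with h through a logistic link f = 1/(1 + exp(k·(h − m))) — an
  explicit modelling stand-in for the DLVO minimum-depth → aggregation
  mapping, chosen so SD is monotone in h and near-linear over the working
  range, not derived from first principles;
* a spectrum is the f-weighted sum of two unit-peak Gaussian bands at the
  profile's stable and aggregate wavelengths plus i.i.d. photometric noise;
* DLS replicates scatter lognormally around the true Rh.

Everything is reproducible from (config, seed): each bundle consumes one
explicitly seeded RNG stream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .polymer_dimensions import (
    PowerLawModel,
    RH_OVER_RG,
    SQRT6,
    mw_to_h_rms,
)
from .solution_chemistry import InstrumentProfile
from .spectra import Spectrum
from .uncertainty import Measurement

#: Reference scaling law used as the generator's ground truth.
TRUTH_POWER_LAW = PowerLawModel(prefactor=0.0718, exponent=0.5250, r_squared=1.0, n_points=0)

#: Default calibration panel (Da): the 600–12,000 working range, 8 levels.
DEFAULT_MW_PANEL = (600.0, 1000.0, 2000.0, 4000.0, 6000.0, 8000.0, 10000.0, 12000.0)


def _default_profile() -> InstrumentProfile:
    return InstrumentProfile(
        profile_id="aunp16",
        particle_diameter_nm=16.0,
        stable_wavelength_nm=520.0,
        aggregate_wavelength_nm=598.0,
        extinction_coefficient=4.916e8,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic assay.

    band widths are Gaussian sigmas in nm (40/120 keep the two fixed-
    wavelength reads well separated); noise_sd is photometric noise in AU;
    replicate_cv the lognormal coefficient of variation of DLS replicates;
    link_steepness (1/nm) and link_midpoint (nm) parametrise the logistic
    aggregation link.
    """

    profile: InstrumentProfile = field(default_factory=_default_profile)
    band_width_stable: float = 40.0
    band_width_aggregate: float = 120.0
    noise_sd: float = 0.005
    replicate_cv: float = 0.05
    seed: int = 0
    link_steepness: float = 0.10
    link_midpoint: float = 6.0
    wavelength_min: float = 400.0
    wavelength_max: float = 900.0
    wavelength_step: float = 1.0

    def __post_init__(self) -> None:
        if self.band_width_stable <= 0 or self.band_width_aggregate <= 0:
            raise DomainError("band widths must be > 0")
        if self.noise_sd < 0 or self.replicate_cv < 0:
            raise DomainError("noise levels must be >= 0")
        if self.link_steepness <= 0:
            raise DomainError("link steepness must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wavelength_max - self.wavelength_min) / self.wavelength_step)) + 1
        return self.wavelength_min + self.wavelength_step * np.arange(n)


def aggregation_fraction(h_rms: float, config: GeneratorConfig) -> float:
    """Logistic aggregated fraction, strictly decreasing in chain size."""
    if h_rms <= 0:
        raise DomainError(f"h_rms must be > 0, got {h_rms}")
    z = config.link_steepness * (h_rms - config.link_midpoint)
    # numerically stable logistic in both tails
    if z >= 0:
        ez = math.exp(-z)
        return ez / (1.0 + ez)
    return 1.0 / (1.0 + math.exp(z))


def _band(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / width) ** 2)


def simulate_spectrum(
    agg_fraction: float,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "synthetic",
    replicate: int = 0,
    is_blank: bool = False,
) -> Spectrum:
    """Two-band mixture spectrum with weights (1−f, f) plus noise."""
    if not (0.0 <= agg_fraction <= 1.0):
        raise DomainError(f"aggregation fraction must be in [0, 1], got {agg_fraction}")
    if rng is None:
        rng = config.rng()
    grid = config.wavelength_grid()
    p = config.profile
    signal = (1.0 - agg_fraction) * _band(grid, p.stable_wavelength_nm, config.band_width_stable)
    signal = signal + agg_fraction * _band(grid, p.aggregate_wavelength_nm, config.band_width_aggregate)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=grid.size)
    return Spectrum(grid, signal, sample_id=sample_id, replicate=replicate, is_blank=is_blank)


def closed_form_sd(agg_fraction: float, config: GeneratorConfig) -> float:
    """Noise-free stability degree of the mixture model.

    With unit-peak bands, cross-band leakage g_s→a = exp(−Δλ²/2w_s²) and
    g_a→s = exp(−Δλ²/2w_a²), and an f = 0 blank:

        SD = [(1−f) + f·g_a→s] / [f·(1 − g_s→a)].
    """
    if not (0.0 < agg_fraction <= 1.0):
        raise DomainError("closed-form SD needs 0 < f <= 1 (f = 0 is above range)")
    p = config.profile
    dl = p.aggregate_wavelength_nm - p.stable_wavelength_nm
    g_stable_at_agg = math.exp(-0.5 * (dl / config.band_width_stable) ** 2)
    g_agg_at_stable = math.exp(-0.5 * (dl / config.band_width_aggregate) ** 2)
    f = agg_fraction
    return ((1.0 - f) + f * g_agg_at_stable) / (f * (1.0 - g_stable_at_agg))


def simulate_dls(
    mw: float,
    n: int,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """n replicate hydrodynamic radii for a chain of molar mass mw (nm).

    True Rh follows the reference chain relations; replicates carry
    lognormal noise of coefficient of variation replicate_cv.
    """
    if mw <= 0:
        raise DomainError("mw must be > 0")
    if n < 1:
        raise DomainError("need n >= 1 replicates")
    if rng is None:
        rng = config.rng()
    rh_true = RH_OVER_RG * mw_to_h_rms(mw, TRUTH_POWER_LAW) / SQRT6
    if config.replicate_cv == 0:
        return np.full(n, rh_true)
    sigma = math.sqrt(math.log(1.0 + config.replicate_cv**2))
    return rh_true * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


@dataclass(frozen=True)
class SampleBundle:
    """Everything generated for one panel member."""

    label: str
    mw_true: float
    h_rms_true: float
    agg_fraction: float
    spectra: list  # list[Spectrum]
    rh_replicates: np.ndarray
    h_ref: Measurement  # DLS-derived reference chain length (mean ± sd)


@dataclass(frozen=True)
class CalibrationBundle:
    """A complete synthetic calibration experiment."""

    samples: list  # list[SampleBundle]
    blank: Spectrum
    config: GeneratorConfig

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [s.label for s in self.samples],
                "mw_da": [s.mw_true for s in self.samples],
                "h_rms_nm": [s.h_rms_true for s in self.samples],
                "agg_fraction": [s.agg_fraction for s in self.samples],
            }
        )


def make_calibration_dataset(
    mw_panel: Sequence[float] = DEFAULT_MW_PANEL,
    replicates: int = 3,
    config: Optional[GeneratorConfig] = None,
) -> CalibrationBundle:
    """Generate spectra + DLS references for a panel of known molar masses.

    One RNG stream (config.seed) drives the whole bundle, so regenerating
    with the same config is bit-identical.  The blank is the aggregation-
    free (f = 0) sol measured with the same photometric noise.
    """
    if len(mw_panel) < 1:
        raise DomainError("panel must be nonempty")
    if replicates < 1:
        raise DomainError("need >= 1 replicates")
    if config is None:
        config = GeneratorConfig()
    rng = config.rng()
    blank = simulate_spectrum(0.0, config, rng=rng, sample_id="blank", is_blank=True)
    samples = []
    for mw in mw_panel:
        h_true = mw_to_h_rms(float(mw), TRUTH_POWER_LAW)
        f = aggregation_fraction(h_true, config)
        label = f"mw{int(round(mw))}"
        specs = [
            simulate_spectrum(f, config, rng=rng, sample_id=label, replicate=r)
            for r in range(replicates)
        ]
        rh = simulate_dls(float(mw), replicates, config, rng=rng)
        h_vals = rh / RH_OVER_RG * SQRT6
        h_sd = float(h_vals.std(ddof=1)) if len(h_vals) >= 2 else 0.0
        samples.append(
            SampleBundle(
                label=label,
                mw_true=float(mw),
                h_rms_true=h_true,
                agg_fraction=f,
                spectra=specs,
                rh_replicates=rh,
                h_ref=Measurement(float(h_vals.mean()), h_sd),
            )
        )
    return CalibrationBundle(samples=samples, blank=blank, config=config)
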