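"""Linear SD → chain-length calibration and molecular-weight determination.

The assay calibrates the stability degree against the known RMS end-to-end
lengths of a reference PEG panel by ordinary least squares,

    h_rms = slope * SD + intercept,

then determines an unknown by: replicate spectra → per-replicate SD →
mean ± sd → calibrated h_rms → inverted size–mass power law → Mw.  Only the
power law is inverted; the calibration line is always used in the direction
it was fitted.  Uncertainties propagate to first order at every step, and
predictions outside the trained SD range are flagged as extrapolated rather
than refused.  A pooled two-sample t test compares determinations against
reference values.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDenominatorError, DomainError, FitError
from .polymer_dimensions import PowerLawModel, h_rms_to_mw
from .solution_chemistry import InstrumentProfile
from .spectra import Spectrum, replicate_stability
from .uncertainty import Measurement, as_measurement

CALIBRATION_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted SD → h_rms line with the statistics prediction needs.

    sd_mean and sxx (the weighted centre and spread of the training SDs)
    feed the standard OLS prediction variance; valid_range records the SD
    span of the training points so out-of-range predictions can be flagged.
    """

    slope: float  # nm per SD unit
    intercept: float  # nm
    r_squared: float
    residual_sd: float  # nm
    n_points: int
    sd_min: float
    sd_max: float
    sd_mean: float
    sxx: float
    profile_id: str = ""

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise FitError("calibration must rest on >= 3 points")
        if self.residual_sd < 0:
            raise DomainError("residual sd must be >= 0")
        if not (self.sd_min < self.sd_max):
            raise DomainError("valid SD range is empty")

    @property
    def valid_range(self) -> tuple[float, float]:
        return (self.sd_min, self.sd_max)

    def to_json(self) -> str:
        d = {"schema_version": CALIBRATION_SCHEMA_VERSION, **asdict(self)}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        d.pop("schema_version", None)
        return cls(**d)


@dataclass(frozen=True)
class HrmsPrediction:
    """A calibrated chain-length estimate with its extrapolation flag."""

    h_rms: Measurement
    extrapolated: bool


@dataclass(frozen=True)
class MwDetermination:
    """End-to-end result for one unknown sample.

    flag is "in-range", "extrapolated", or "above-range"; in the last case
    (every replicate fully stable, no measurable aggregate band) h_rms and
    mw are None.  sd_sd is None when only one replicate was usable.
    """

    sample_id: str
    sd_mean: Optional[float]
    sd_sd: Optional[float]
    h_rms: Optional[Measurement]
    mw: Optional[Measurement]
    flag: str
    n_replicates: int


@dataclass(frozen=True)
class MethodComparison:
    statistic: float
    pvalue: float
    df: float


def fit_calibration(
    sd_values: Sequence["Measurement | float"],
    h_rms_values: Sequence["Measurement | float"],
    profile: "InstrumentProfile | None" = None,
) -> CalibrationModel:
    """OLS of h_rms on SD over the reference panel.

    Input uncertainties are accepted for bookkeeping but the line itself is
    an unweighted fit (the calibration convention); scatter about the line
    enters predictions through residual_sd.
    """
    x = np.array([as_measurement(v).value for v in sd_values], dtype=float)
    y = np.array([as_measurement(v).value for v in h_rms_values], dtype=float)
    if x.size != y.size:
        raise FitError("sd and h_rms lists differ in length")
    if x.size < 3:
        raise FitError(f"calibration needs >= 3 points, got {x.size}")
    if np.allclose(x, x[0]):
        raise FitError("degenerate calibration: all SD values identical")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = x.size - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_sd=residual_sd,
        n_points=int(x.size),
        sd_min=float(x.min()),
        sd_max=float(x.max()),
        sd_mean=float(x.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
        profile_id=profile.profile_id if profile is not None else "",
    )


def predict_h_rms(sd: "Measurement | float", model: CalibrationModel) -> HrmsPrediction:
    """Calibrated h_rms for a measured SD, with OLS prediction variance.

    var(h) = slope^2 var(SD) + s^2 (1 + 1/n + (SD - SD_mean)^2 / Sxx)
    with s the residual sd — the usual new-observation prediction variance,
    smallest at the training mean.  Out-of-range SDs are flagged.
    """
    sd = as_measurement(sd)
    h = model.slope * sd.value + model.intercept
    line_term = 1.0 + 1.0 / model.n_points
    if model.sxx > 0:
        line_term += (sd.value - model.sd_mean) ** 2 / model.sxx
    var = model.slope**2 * sd.sd**2 + model.residual_sd**2 * line_term
    extrapolated = not (model.sd_min <= sd.value <= model.sd_max)
    return HrmsPrediction(Measurement(h, math.sqrt(var)), extrapolated)


def determine_mw(
    sample_spectra: Sequence[Spectrum],
    blank: Spectrum,
    model: CalibrationModel,
    powerlaw: PowerLawModel,
    profile: InstrumentProfile,
    sample_id: str = "",
) -> MwDetermination:
    """Full determination for one unknown from its replicate spectra."""
    if len(sample_spectra) < 1:
        raise DomainError("need at least one replicate spectrum")
    if not sample_id:
        sample_id = sample_spectra[0].sample_id
    try:
        sd_summary, values, _ = replicate_stability(sample_spectra, blank, profile)
    except DegenerateDenominatorError:
        return MwDetermination(
            sample_id=sample_id,
            sd_mean=None,
            sd_sd=None,
            h_rms=None,
            mw=None,
            flag="above-range",
            n_replicates=len(sample_spectra),
        )
    prediction = predict_h_rms(sd_summary, model)
    mw = h_rms_to_mw(prediction.h_rms, powerlaw)
    return MwDetermination(
        sample_id=sample_id,
        sd_mean=sd_summary.value,
        sd_sd=sd_summary.sd if len(values) >= 2 else None,
        h_rms=prediction.h_rms,
        mw=mw,
        flag="extrapolated" if prediction.extrapolated else "in-range",
        n_replicates=len(values),
    )


def compare_methods(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    welch: bool = False,
) -> MethodComparison:
    """Two-sample two-tailed t test from summary statistics.

    Pooled-variance Student's t by default (df = n_a + n_b - 2); Welch's
    unequal-variance form behind the ``welch`` flag.
    """
    if n_a < 2 or n_b < 2:
        raise DomainError("each group needs n >= 2")
    if sd_a <= 0 or sd_b <= 0:
        raise DomainError("group sds must be > 0")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=not welch
    )
    if welch:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    else:
        df = n_a + n_b - 2
    return MethodComparison(float(res.statistic), float(res.pvalue), float(df))
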