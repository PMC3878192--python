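"""Packaged reference data: the PEG reference panel, the published
colorimetric determinations, instrument profiles and the reference scaling
law.  All loaders return fresh objects built from the CSV/JSON files
shipped inside the package.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .polymer_dimensions import PolymerSample, PowerLawModel
from .solution_chemistry import InstrumentProfile
from .uncertainty import Measurement


def _data_path(name: str):
    return resources.files("pegcal").joinpath("data", name)


def reference_panel() -> pd.DataFrame:
    """The 14-sample PEG reference panel: label, source, Mw ± sd, Rh ± sd.

    Mw values are SEC/MALLS weight averages; Rh values are DLS triplicate
    means in 81.5 mM NaCl.
    """
    with resources.as_file(_data_path("peg_reference_panel.csv")) as p:
        return pd.read_csv(p)


def reference_panel_derived() -> pd.DataFrame:
    """Published derived columns (Rg, h_rms) of the reference panel, as
    printed by the source study — used for cross-checks against the
    package's own conversions."""
    with resources.as_file(_data_path("peg_reference_derived.csv")) as p:
        return pd.read_csv(p)


def reference_samples(source: "str | None" = None) -> list[PolymerSample]:
    """The reference panel as PolymerSample objects (rg/h_rms derived).

    source="APEG" restricts to the ten-sample calibration series,
    source="SPEG" to the four validation samples.
    """
    df = reference_panel()
    if source is not None:
        df = df[df["source"] == source]
    return [
        PolymerSample.from_dls(
            row.label,
            Measurement(float(row.mw_da), float(row.mw_sd)),
            Measurement(float(row.rh_nm), float(row.rh_sd)),
        )
        for row in df.itertuples()
    ]


def colorimetric_determinations() -> pd.DataFrame:
    """Published colorimetric h_rms and Mw determinations of the four
    validation samples on both particle sizes (triplicate mean ± sd)."""
    with resources.as_file(_data_path("colorimetric_determinations.csv")) as p:
        return pd.read_csv(p)


def instrument_profile(which: str = "16nm") -> InstrumentProfile:
    """Packaged optical profile of the 16-nm or 26-nm particle batch."""
    name = {"16nm": "profile_16nm.json", "26nm": "profile_26nm.json"}.get(which)
    if name is None:
        raise KeyError(f"unknown profile {which!r}; use '16nm' or '26nm'")
    return InstrumentProfile.from_json(_data_path(name).read_text())


def reference_power_law() -> PowerLawModel:
    """The published size–mass scaling law h = 0.0718·Mw^0.525."""
    return PowerLawModel.from_json(_data_path("power_law_reference.json").read_text())
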