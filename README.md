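# pegcal

Molecular-weight determination of polyethylene glycol (PEG) from a
gold-nanoparticle colorimetric aggregation assay.

## The problem

PEG's molar mass controls its behaviour as an excipient and as a
drug-conjugate polymer, but the standard determinations (SEC/MALLS, NMR,
MALDI-TOF) need instruments many labs don't have. A cheap alternative:
citrate-stabilised gold nanoparticles (AuNPs) coated with PEG survive a
salt challenge in proportion to the thickness of the adsorbed polymer
layer, which tracks the chain's size in solution. The sol's colour — wine
red when dispersed, blue when aggregated — turns a UV–vis spectrophotometer
into a molecular-weight meter.

`pegcal` implements that analysis end to end for people who run (or
simulate) the assay:

* **stability degree** — from a spectrum of a salt-challenged sol,
  `SD = A(λ_stable) / [A(λ_agg) − A⁰(λ_agg)]`, the stable-peak absorbance
  over the blank-corrected aggregate-peak absorbance (λ = 520/598 nm for
  16-nm particles, 524/790 nm for 26-nm);
* **chain dimensions** — ideal-chain conversions `R_h = 0.85·R_g`,
  `⟨h²⟩^½ = √6·R_g`, and the scaling law `⟨h²⟩^½ = a·M_w^ν` fitted on a
  reference panel (ν ≈ 0.525 for PEG below ~80 kDa, close to the θ-solvent
  value 0.5);
* **calibration** — ordinary least squares of `⟨h²⟩^½` on SD, then
  determination of unknowns by inverting only the power law, with
  first-order uncertainty propagation and extrapolation flags;
* **solution chemistry** — salt-spike molarity, Debye screening length
  `κ⁻¹ = 0.3041/(z√C)` nm, Beer–Lambert particle concentration, surface
  area, and polymer-saturation checks;
* **screened DLVO model** — `U_total = U_steric + U_vdW` (electrostatics
  screened to zero by the salt), secondary-minimum location/depth and a
  stability classification, rationalising why adlayer thickness sets
  stability;
* **synthetic data** — a generator for two-band plasmon spectra, DLS
  replicates and whole calibration experiments, so the entire pipeline is
  testable with no instrument.

## Worked example

```python
import numpy as np
import pegcal
from pegcal import datasets, GeneratorConfig
from pegcal.spectra import replicate_stability
from pegcal.synthetic_data import TRUTH_POWER_LAW, aggregation_fraction
from pegcal.polymer_dimensions import mw_to_h_rms

# 1. refit the size-mass scaling law on the packaged reference panel
apeg = datasets.reference_samples("APEG")
law = pegcal.fit_power_law(apeg)

# 2. calibrate SD -> chain length on a simulated 8-level panel
profile = datasets.instrument_profile("16nm")
config = GeneratorConfig(profile=profile, seed=1)
bundle = pegcal.make_calibration_dataset(config=config)
cal = pegcal.fit_calibration(
    [replicate_stability(s.spectra, bundle.blank, profile)[0] for s in bundle.samples],
    [s.h_ref for s in bundle.samples], profile=profile)

# 3. determine an unknown (true Mw 5000 Da) from triplicate spectra
rng = np.random.default_rng(7)
f = aggregation_fraction(mw_to_h_rms(5000.0, TRUTH_POWER_LAW), config)
spectra = [pegcal.simulate_spectrum(f, config, rng=rng, replicate=r) for r in range(3)]
det = pegcal.determine_mw(spectra, bundle.blank, cal, law, profile)
```

which prints, with the formatting used in the repository's examples:

```
scaling law: h = 0.0722 * Mw^0.5245  (R2 = 0.9979)
calibration: h = 7.651*SD -10.909  (R2 = 0.981)
unknown: SD = 2.178 +/- 0.048, h = 5.76 +/- 0.58 nm, Mw = 4228 +/- 816 Da (in-range)
```

Reading the numbers: the ten-sample reference panel gives a scaling
exponent of 0.5245 — PEG behaves nearly as an ideal chain. The simulated
calibration line maps stability degree to chain length with R² ≈ 0.98, and
the triplicate determination of the synthetic unknown lands at
4.2 ± 0.8 kDa against a true value of 5 kDa, inside its one-sigma band and
within the ~15% accuracy the assay supports.

The same operations are available from the shell:

```
pegcal chem spike --spike-ul 50        # -> 81.5 mM
pegcal chem debye --molarity 0.0815    # -> 1.07 nm
pegcal simulate --out sim/ --seed 7
pegcal sd --sample sim/mw6000_rep0.csv --blank sim/blank.csv
pegcal calibrate --pairs pairs.csv --out cal.json
pegcal predict --sample s1.csv --sample s2.csv --blank blank.csv --calibration cal.json
pegcal dlvo --params params.json --sweep t=1:13:0.5
```

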