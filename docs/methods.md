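# Methods

This note records the models pegcal implements, the numerical and design
choices behind them, and what the synthetic tests do and do not establish.

## Chain dimensions and the scaling law

For flexible PEG coils in water the package uses the two ideal-chain
constants: `R_g = R_h / 0.85` (DLS radius to gyration radius) and
`⟨h²⟩^½ = √6 · R_g` (gyration radius to RMS end-to-end length). Both are
exact multiplicative conversions, so one-sigma uncertainties scale by the
same factors. `PolymerSample` refuses derived columns that disagree with
these constants beyond 0.5% — the container stores a consistent set, not
three independent measurements.

Across a homologous series, size scales as `⟨h²⟩^½ = a · M_w^ν`.
`fit_power_law` fits this as a straight line in log–log space. When every
point carries a positive size uncertainty the fit is weighted by
`1/σ²` with `σ = h_sd/h` (the log-space transform of the error bar) — the
instrumental weighting a spreadsheet fit against error bars applies, and
the variant that reproduces the reference panel's published coefficients
(ν = 0.5245, a = 0.0722 nm·Da⁻ᵛ on the ten-sample panel; an unweighted fit
of the same points gives 0.509/0.082 because the two noisiest mid-panel
points pull the line). Equal uncertainties reduce the weighted fit to
plain OLS, which is also available explicitly, as is a nonlinear fit in
linear space (`space="linear"`). The reported R² is that of the
(possibly weighted) log-space fit; no claim is made about R² in other fit
spaces.

Inversion is `M_w = (h/a)^{1/ν}` with the delta-method uncertainty
`sd_M = M · sd_h/(ν h)`. Exponents are restricted to (0, 1): below ~80 kDa
PEG sits near the θ-solvent value 0.5, and the container rejects
unphysical fits loudly rather than propagating them.

## Solution chemistry

Fixed constants: Avogadro 6.02214×10²³ mol⁻¹, NaCl 58.44 g/mol. Spike
molarity treats volumes as additive (no excess-volume correction — the
spikes are ≤6% of the sample volume). The Debye length uses the
water-at-25 °C closed form `κ⁻¹ = 0.3041/(z√C)` nm, valid for a single
symmetric electrolyte; zero molarity raises rather than returning an
infinite screening length. Particle concentration is Beer–Lambert
`A/(ε·l)` with the batch extinction coefficient taken as an instrument
constant (no Mie calculation). Surface area uses the dry TEM diameter,
matching how the reference concentrations were derived. The saturation
check counts one molecule per `π R_h²` footprint and reports the excess as
log₁₀; with the standard loading (11.25 mg/mL) the excess is ~10^4.5 for
the smallest chain in the panel — large, though closer to 4.5 than 5
orders of magnitude under this footprint convention.

## The screened DLVO model

With the electrostatic term screened to zero by the salt,
`U_total = U_steric + U_vdW`. The steric repulsion between cores of radius
R with adlayers of thickness t is `U₀·B(y)` for `2R ≤ L < 2R+2t`,
`y = (L−2R)/2t`, with

    B(y) = −ln y − (9/5)(1−y) + (1/3)(1−y)³ − (1/30)(1−y)⁶
    U₀   = (π³/12) σ_p N_p l² (R/t) k_BT

a +∞ sentinel for core overlap, and zero once the layers separate
(`U_steric(H=2t) = 0` anchors the upper bound of the overlap branch). The
U₀ grouping above is the only reading of the model's symbol string that is
dimensionally an energy; it is stated here once and tested against a hand
computation. Two genuine properties of this B deserve emphasis:

* it diverges logarithmically at core contact and decreases steeply on
  the inner region, but
* it is **not** monotone on (0, 1]: its expansion at y = 1 begins
  −(4/5)(1−y), so the profile dips to a shallow negative lobe of depth
  0.18806·U₀ at y = 0.6070 before vanishing at layer contact. The onset of
  layer overlap is therefore weakly attractive in this model. The tests
  assert the lobe's value rather than pretending the term is purely
  repulsive.

`U_vdW = −A*R/(12H)` (Derjaguin sphere–sphere), converted from joules to
k_BT at the model temperature. Because −1/H beats −ln H at contact, the
continuum curve is unbounded below at H → 0 (the primary minimum); a
"global minimum over the grid" would just report the grid floor.
`find_minimum` therefore returns the **secondary minimum** — the outermost
strictly negative local minimum, located on a 2000-point grid over
H ∈ (0, 6t] and polished by bounded scalar minimisation to 10⁻¹⁰ nm. This
is the well a particle arriving from infinity actually samples, and it is
the quantity for which the assay's mechanistic claim holds: its depth is
non-increasing in adlayer thickness (verified over 20-point sweeps), so
thick adlayers mean stable sols. `classify_stability` calls a dispersion
aggregating when the well is deeper than 3 k_BT — a convention of order
thermal energy, user-overridable, not a fitted constant.

The chain parameters σ_p, N_p, l and the coated-particle Hamaker constant
A* are free inputs; no published values exist for this system. Tests and
CLI examples use σ_p = 0.5 nm⁻², N_p = 50, l = 0.35 nm, A* = 10⁻²⁰ J —
typical literature magnitudes for PEG on gold in water — and all asserted
properties are monotonicity/limit statements that do not depend on the
specific values.

## Spectra and the stability degree

Spectra are strictly-increasing wavelength grids; unsorted input is sorted
with a warning, duplicates are rejected. Absorbance queries use linear
interpolation — spectrophotometer output is ~1 nm dense, so higher-order
schemes change nothing at the 10⁻⁴ AU level (tested against an analytic
band). Normalization divides by the peak; SD is a within-spectrum ratio,
so it is invariant under normalization and under any common rescaling of
sample and blank.

`SD = A(λ_s) / [A(λ_a) − A⁰(λ_a)]` subtracts the blank (the same sol
diluted with water instead of salt) in the denominator only — at the
aggregate wavelength the blank measures the stable band's tail, which is
exactly the non-aggregation background. A denominator at or below 10⁻⁶ AU
raises a dedicated error: the sample is then fully stable and the assay
cannot rank it (the long-chain regime where the sol never turns blue).
Replicates are summarised as mean ± sample sd; a single replicate reports
no scatter and downstream uncertainty comes from the calibration residual
alone.

## Calibration and determination

The calibration is OLS of `⟨h²⟩^½` on SD, fitted in that direction and
never inverted; only the power law is inverted. The model stores the
residual sd, the training-SD mean and spread, and the trained SD range.
Prediction variance is the standard new-observation form

    var(h) = slope²·var(SD) + s²·(1 + 1/n + (SD − SD̄)²/Sxx)

minimal at the training mean and growing toward the edges; predictions
outside the trained range are flagged `extrapolated`, not refused. The
method comparison is a pooled two-sample Student's t from summary
statistics (the convention for triplicate bench data), with Welch's
variant behind a flag.

## The synthetic generator

The generator emulates the assay's statistical structure, not its
photophysics:

* **truth chain**: `h = 0.0718·M_w^0.525`, `R_h = 0.85·h/√6`;
* **aggregation link**: `f(h) = 1/(1+exp(k(h−m)))`, strictly decreasing —
  an explicit stand-in for the minimum-depth → aggregation mapping, with
  defaults k = 0.10 nm⁻¹ and m = 6 nm. m centres the link on the assay's
  1.9–10.2 nm working range; k was chosen so the default panel's SD–h
  relation is near-linear (calibration R² ≈ 0.98, matching the 0.98–0.999
  linearity the assay exhibits). Steeper links (k ≥ 0.15) curve the
  relation visibly and misrepresent the regime the assay operates in. The
  link is a modelling choice: the real SD↔aggregation mapping is
  constrained only by monotonicity;
* **spectra**: unit-peak Gaussian bands at the profile's two wavelengths,
  weights (1−f, f), widths 40/120 nm (keeping the two fixed-wavelength
  reads well separated), plus i.i.d. photometric noise of sd 0.005 AU on a
  400–900 nm, 1-nm grid. Real plasmon bands are asymmetric and their
  aggregate band drifts red with cluster size; none of that is modelled,
  so passing tests certify the statistics of the pipeline, not instrument
  realism;
* **DLS**: lognormal replicate noise with cv 0.05 (the reference panel's
  relative sds are mostly 2–9%), mean-preserving parametrisation;
* **determinism**: one `numpy` Generator per bundle seeded from the
  config; identical configs regenerate bit-identical bundles.

Default experiment sizes — an 8-level panel (600–12,000 Da, the working
range), triplicate spectra, 50 held-out unknowns for recovery studies —
keep every simulation-backed test and script in the seconds range while
leaving the statistics stable across seeds (recovery medians 6–10% and
unbiased signs were checked over several seeds before freezing the
defaults).

## Known limitations

* The assay saturates outside ~1.9–10.2 nm (roughly 600–12,000 Da): very
  short chains precipitate before the read, very long chains never leave
  the blank's dynamic range. pegcal reports these as errors/flags rather
  than numbers.
* First-order propagation only: no Fieller-type inverse-regression
  intervals, no bootstrap. The ± values are one-sigma delta-method
  estimates.
* The DLVO module is a rationalisation tool, not a predictor: with σ_p,
  N_p, l, A* unknown, only its qualitative structure (sweep monotonicity,
  limits) is testable.
* The steric profile's shallow attractive lobe is a property of the model
  as published; a strictly repulsive profile would change the secondary
  minimum quantitatively (not qualitatively) and is deliberately not
  substituted.
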