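{
  "profile_id": "aunp16",
  "particle_diameter_nm": 16.0,
  "stable_wavelength_nm": 520.0,
  "aggregate_wavelength_nm": 598.0,
  "extinction_coefficient": 4.916e8,
  "path_length_cm": 1.0
}
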