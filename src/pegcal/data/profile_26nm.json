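{
  "profile_id": "aunp26",
  "particle_diameter_nm": 26.0,
  "stable_wavelength_nm": 524.0,
  "aggregate_wavelength_nm": 790.0,
  "extinction_coefficient": 2.465e9,
  "path_length_cm": 1.0
}
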