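{
  "prefactor": 0.0718,
  "exponent": 0.5250,
  "r_squared": 0.9994,
  "n_points": 10
}
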