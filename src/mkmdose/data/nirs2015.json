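{
  "schema": "mkmdose/params-v1",
  "parameters": {
    "alpha0": {
      "value": 0.172,
      "unit": "Gy^-1"
    },
    "beta": {
      "value": 0.0615,
      "unit": "Gy^-2"
    },
    "alpha_r": {
      "value": 0.764,
      "unit": "Gy^-1"
    },
    "f_clin": {
      "value": 2.41,
      "unit": "dimensionless"
    },
    "domain_radius": {
      "value": 0.32,
      "unit": "um"
    },
    "nucleus_radius": {
      "value": 3.9,
      "unit": "um"
    },
    "zstar_ref": {
      "value": 9.626016260162602,
      "unit": "Gy"
    }
  }
}
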