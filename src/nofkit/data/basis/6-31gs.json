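{
  "name": "6-31g*",
  "comment": "6-31G plus a single spherical d polarization shell on heavy atoms (alpha_d = 0.8).",
  "extends": "6-31g",
  "elements": {
    "O": [{"l": 2, "exps": [0.8], "coefs": [1.0]}]
  }
}
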