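{
  "name": "6-31g",
  "comment": "Split-valence 6-31G basis, standard published values (subset of elements used by the bundled fixtures).",
  "elements": {
    "H": [{"l": 0, "exps": [18.7311370, 2.8253937, 0.6401217],
           "coefs": [0.03349460, 0.23472695, 0.81375733]},
          {"l": 0, "exps": [0.1612778], "coefs": [1.0]}],
    "O": [{"l": 0, "exps": [5484.6717, 825.23495, 188.04696, 52.964500, 16.897570, 5.7996353],
           "coefs": [0.00183110, 0.01395010, 0.06844510, 0.23271430, 0.47019300, 0.35852090]},
          {"l": 0, "exps": [15.539616, 3.5999336, 1.0137618],
           "coefs": [-0.11077750, -0.14802630, 1.13076700]},
          {"l": 1, "exps": [15.539616, 3.5999336, 1.0137618],
           "coefs": [0.07087430, 0.33975280, 0.72715860]},
          {"l": 0, "exps": [0.2700058], "coefs": [1.0]},
          {"l": 1, "exps": [0.2700058], "coefs": [1.0]}]
  }
}
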