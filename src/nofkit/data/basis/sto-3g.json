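{
  "name": "sto-3g",
  "comment": "Minimal STO-3G basis, standard published least-squares STO expansions (scaled universal 1s/2sp sets).",
  "elements": {
    "H":  [{"l": 0, "exps": [3.42525091, 0.62391373, 0.16885540],
            "coefs": [0.15432897, 0.53532814, 0.44463454]}],
    "He": [{"l": 0, "exps": [6.36242139, 1.15892300, 0.31364979],
            "coefs": [0.15432897, 0.53532814, 0.44463454]}],
    "Li": [{"l": 0, "exps": [16.1195750, 2.9362007, 0.7946505],
            "coefs": [0.15432897, 0.53532814, 0.44463454]},
           {"l": 0, "exps": [0.6362897, 0.1478601, 0.0480887],
            "coefs": [-0.09996723, 0.39951283, 0.70011547]},
           {"l": 1, "exps": [0.6362897, 0.1478601, 0.0480887],
            "coefs": [0.15591627, 0.60768372, 0.39195739]}],
    "Be": [{"l": 0, "exps": [30.1678710, 5.4951153, 1.4871927],
            "coefs": [0.15432897, 0.53532814, 0.44463454]},
           {"l": 0, "exps": [1.3148331, 0.3055389, 0.0993707],
            "coefs": [-0.09996723, 0.39951283, 0.70011547]},
           {"l": 1, "exps": [1.3148331, 0.3055389, 0.0993707],
            "coefs": [0.15591627, 0.60768372, 0.39195739]}],
    "B":  [{"l": 0, "exps": [48.7911130, 8.8873622, 2.4052670],
            "coefs": [0.15432897, 0.53532814, 0.44463454]},
           {"l": 0, "exps": [2.2369561, 0.5198205, 0.1690618],
            "coefs": [-0.09996723, 0.39951283, 0.70011547]},
           {"l": 1, "exps": [2.2369561, 0.5198205, 0.1690618],
            "coefs": [0.15591627, 0.60768372, 0.39195739]}],
    "C":  [{"l": 0, "exps": [71.6168370, 13.0450960, 3.5305122],
            "coefs": [0.15432897, 0.53532814, 0.44463454]},
           {"l": 0, "exps": [2.9412494, 0.6834831, 0.2222899],
            "coefs": [-0.09996723, 0.39951283, 0.70011547]},
           {"l": 1, "exps": [2.9412494, 0.6834831, 0.2222899],
            "coefs": [0.15591627, 0.60768372, 0.39195739]}],
    "N":  [{"l": 0, "exps": [99.1061690, 18.0523120, 4.8856602],
            "coefs": [0.15432897, 0.53532814, 0.44463454]},
           {"l": 0, "exps": [3.7804559, 0.8784966, 0.2857144],
            "coefs": [-0.09996723, 0.39951283, 0.70011547]},
           {"l": 1, "exps": [3.7804559, 0.8784966, 0.2857144],
            "coefs": [0.15591627, 0.60768372, 0.39195739]}],
    "O":  [{"l": 0, "exps": [130.7093200, 23.8088610, 6.4436083],
            "coefs": [0.15432897, 0.53532814, 0.44463454]},
           {"l": 0, "exps": [5.0331513, 1.1695961, 0.3803890],
            "coefs": [-0.09996723, 0.39951283, 0.70011547]},
           {"l": 1, "exps": [5.0331513, 1.1695961, 0.3803890],
            "coefs": [0.15591627, 0.60768372, 0.39195739]}],
    "F":  [{"l": 0, "exps": [166.6791300, 30.3608120, 8.2168207],
            "coefs": [0.15432897, 0.53532814, 0.44463454]},
           {"l": 0, "exps": [6.4648032, 1.5022812, 0.4885885],
            "coefs": [-0.09996723, 0.39951283, 0.70011547]},
           {"l": 1, "exps": [6.4648032, 1.5022812, 0.4885885],
            "coefs": [0.15591627, 0.60768372, 0.39195739]}],
    "Ne": [{"l": 0, "exps": [207.0156100, 37.7081510, 10.2052970],
            "coefs": [0.15432897, 0.53532814, 0.44463454]},
           {"l": 0, "exps": [8.2463151, 1.9162662, 0.6232293],
            "coefs": [-0.09996723, 0.39951283, 0.70011547]},
           {"l": 1, "exps": [8.2463151, 1.9162662, 0.6232293],
            "coefs": [0.15591627, 0.60768372, 0.39195739]}]
  }
}
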