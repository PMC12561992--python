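{
 "kform": 1.01,
 "kloss": 4.61,
 "nf": 4.0,
 "yNumber_ss1": 7.0,
 "yNumber_ss2": 4.02,
 "ks": 65.9,
 "kd": 2.04,
 "pMLC0": 0.0,
 "yDiameter0": 47.91,
 "tau_pMLC": 400.0
}
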