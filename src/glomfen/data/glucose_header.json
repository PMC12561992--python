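{
 "slope": 0.051,
 "intercept": -9.38,
 "gmax_mmol_l": 33.46,
 "gmax_policy": "linear prediction at week 5 (normalized glucose activity reaches 1 at 840 h)",
 "seed": 0
}
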