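t_start_h,t_end_h,mean_mmol_l,sd_mmol_l
1008,1176,43.0,3.0
1176,1344,43.0,3.0
1344,1512,43.0,3.0
1512,1680,43.0,3.0
1680,1848,43.0,3.0
1848,2016,43.0,3.0
2016,2352,43.0,3.0
2352,2688,43.0,3.0
2688,3024,43.0,3.0
3024,3360,43.0,3.0
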