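parameter	value
slope	566488
intercept	2302.2
range_low_ng_ml	7.81
range_high_ng_ml	125
r_squared	0.9962
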