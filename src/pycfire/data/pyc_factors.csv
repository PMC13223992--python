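fuel_category,p_pyc,ci_low,ci_high
NWF,0.110,0.070,0.150
FWF,0.170,0.100,0.240
CWF,0.260,0.180,0.340
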