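fuel_category,cc_min,cc_max
NWF,0.70,1.00
FWF,0.40,0.70
CWF,0.20,0.50
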