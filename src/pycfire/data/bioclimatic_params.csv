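bioclimatic_class,ef_co2,dmcc
tropical,1643.0,0.49
temperate,1647.0,0.47
boreal,1489.0,0.45
savanna,1686.0,0.45
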