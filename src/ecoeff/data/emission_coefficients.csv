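source,coefficient,unit
pesticides,4.9341,kg/kg
fertilizer,0.8956,kg/kg
diesel,0.5927,kg/kg
agricultural_film,5.18,kg/kg
irrigation,266.48,kg/hm2
tillage,312.6,kg/hm2
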