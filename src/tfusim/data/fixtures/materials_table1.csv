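site,thickness_mm,quantity,value,units,provenance,citation
scalp,,speed_of_sound,1450,m/s,literature,Head model material parameters table
scalp,,attenuation_coefficient,68,dB/m,literature,Head model material parameters table
scalp,,density,955,kg/m^3,literature,Head model material parameters table
skull,,speed_of_sound,4080,m/s,literature,Head model material parameters table
skull,,attenuation_coefficient,2000,dB/m,literature,Head model material parameters table
skull,,density,1658,kg/m^3,literature,Head model material parameters table
brain,,speed_of_sound,1552,m/s,literature,Head model material parameters table
brain,,attenuation_coefficient,85,dB/m,literature,Head model material parameters table
brain,,density,1046,kg/m^3,literature,Head model material parameters table
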