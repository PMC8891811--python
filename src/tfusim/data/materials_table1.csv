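name,speed_of_sound_mps,attenuation_db_per_m,density_kg_per_m3
water,1482,0,998
scalp,1450,68,955
skull,4080,2000,1658
brain,1552,85,1046
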