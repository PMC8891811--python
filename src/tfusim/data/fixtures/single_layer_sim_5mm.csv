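site,thickness_mm,quantity,value,units,provenance,citation
scalp,5,attenuation_percent,3.78,%,simulation,single-layer model at unified 5 mm thickness
skull,5,attenuation_percent,85.45,%,simulation,single-layer model at unified 5 mm thickness
brain,5,attenuation_percent,5.54,%,simulation,single-layer model at unified 5 mm thickness
scalp,5,focal_peak,2.19,MPa,simulation,single-layer model at unified 5 mm thickness
skull,5,focal_peak,0.382,MPa,simulation,single-layer model at unified 5 mm thickness
brain,5,focal_peak,2.15,MPa,simulation,single-layer model at unified 5 mm thickness
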