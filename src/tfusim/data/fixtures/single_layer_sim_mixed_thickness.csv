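site,thickness_mm,quantity,value,units,provenance,citation
scalp,3.35,attenuation_percent,3.21,%,simulation,single-layer model at anatomical thicknesses
skull,5,attenuation_percent,83.22,%,simulation,single-layer model at anatomical thicknesses
brain,40,attenuation_percent,34.49,%,simulation,single-layer model at anatomical thicknesses
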