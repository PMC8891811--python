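site,thickness_mm,quantity,value,units,provenance,citation
scalp,3.35,attenuation_percent,12.10,%,phantom,single-layer pigskin on transducer
skull,5,attenuation_percent,85.45,%,phantom,single-layer skull No. 14 on transducer
brain,40,attenuation_percent,18.20,%,phantom,single-layer brain tissue phantom on transducer
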