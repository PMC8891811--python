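site,thickness_mm,quantity,value,units,provenance,citation
S1,3.5,attenuation_percent,69.60,%,phantom,skull No. 14 test point S1 (frontal bone)
S2,4.5,attenuation_percent,76.80,%,phantom,skull No. 14 test point S2 (frontal bone)
S3,5,attenuation_percent,82.40,%,phantom,skull No. 14 test point S3
S4,6.5,attenuation_percent,86.40,%,phantom,skull No. 14 test point S4
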