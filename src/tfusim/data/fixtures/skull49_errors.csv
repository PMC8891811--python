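site,thickness_mm,quantity,value,units,provenance,citation
S5,7.1,model_relative_error,1.99,%,phantom,skull No. 49 frontal-bone test point S5 (raw pressures not published)
S6,7.1,model_relative_error,2.44,%,phantom,skull No. 49 frontal-bone test point S6 (raw pressures not published)
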