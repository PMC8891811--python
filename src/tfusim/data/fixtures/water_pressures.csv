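site,thickness_mm,quantity,value,units,provenance,citation
100V,,free_water_focal_peak,0.862,MPa,phantom,water-tank hydrophone measurement at 100 V excitation
200V,,free_water_focal_peak,1.931,MPa,phantom,water-tank hydrophone measurement at 200 V excitation
300V,,free_water_focal_peak,2.138,MPa,phantom,water-tank hydrophone measurement at 300 V excitation
400V,,free_water_focal_peak,2.276,MPa,phantom,water-tank hydrophone measurement at 400 V excitation
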