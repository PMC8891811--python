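site,thickness_mm,quantity,value,units,provenance,citation
water,,focal_peak,2.276,MPa,simulation,pure-water reference at 400 V calibration
water,,focal_peak,2.276,MPa,phantom,pure-water reference at 400 V excitation
multilayer,,focal_peak,0.219,MPa,simulation,multilayer head model (3.35 mm scalp + 5 mm skull + 40 mm brain)
multilayer,,focal_peak,0.255,MPa,phantom,multilayer head phantom (pigskin + skull No. 14 + brain gel)
multilayer,,attenuation_percent,90.1,%,simulation,multilayer head model vs pure water
multilayer,,attenuation_percent,88.8,%,phantom,multilayer head phantom vs pure water
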