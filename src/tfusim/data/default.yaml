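# Default axisymmetric simulation setup: 1 MHz, 46 mm aperture focused bowl
# radiating upward (+z) through water and a stack of homogeneous tissue slabs.
transducer:
  center_frequency_hz: 1.0e6
  aperture_diameter_m: 0.046
  curvature_radius_m: 0.090
  drive_amplitude_pa: 1.0

grid:
  spacing_m: 5.0e-5          # ~30 points per water wavelength at 1 MHz
  radial_extent_m: 0.030
  axial_extent_m: 0.120

pml:
  thickness_m: 1.5e-3        # ~1 water wavelength
  target_reflection: 1.0e-4
  profile_order: 2

geometry:
  source_margin_m: 2.0e-3    # gap between bottom PML and the bowl apex
  standoff_m: 0.010          # water gap between bowl apex and first layer
  peak_margin_m: 1.5e-3      # distal exclusion band behind the last interface

# Tissue slabs in source-to-far-field order; thicknesses in metres.
# An empty list is the pure-water free-field reference.
layers: []

materials: null               # null -> packaged head-tissue table
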