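# Default physical constants and stylised lens-design presets.
#
# The two commercial enhanced-monofocal designs the bench emulates are
# proprietary; the presets below are documented stand-ins that reproduce
# the *mechanism* of each family (a central add-power zone with a gradual
# transition to a monofocal periphery, vs. a centre that amplifies the
# positive corneal spherical aberration), not the actual lens surfaces.

physical:
  vertex_distance_mm: 12.0        # spectacle plane to corneal plane
  eye_focal_length_mm: 17.2       # image-space focal length of the model eye
  cornea:
    sa_coefficient_um: 0.27       # primary SA Z(4,0) of the model cornea
    reference_diameter_mm: 5.15   # aperture at which the coefficient holds

csf:
  peak_frequency_cpd: 6.0         # neural CSF peak, cycles/degree
  low_frequency_exponent: 2.0     # power-law rise below the peak
  calibration_logmar: 0.04        # diffraction-limited 3-mm best-focus simVA

acuity:
  exponent_b: -0.36               # simVA = wOTF ** b
  monocular_reduction: 0.07       # binocular -> monocular decimal-acuity factor

presets:
  quantum_like:                   # central add-power zone family
    family: central_add_zone
    add_power_D: 0.9
    zone_radius_mm: 1.0
    transition_width_mm: 0.5
    sa_coefficient_um: -0.1       # corneal-SA-correcting, at 6 mm
    sa_reference_diameter_mm: 6.0
    sa_power_slope_um_per_D: 0.0
    abbe_number: 41
  emv_like:                       # SA-amplifying family
    family: sa_amplifying
    add_power_D: 0.0
    zone_radius_mm: 0.0
    transition_width_mm: 0.0
    sa_coefficient_um: 0.15       # adds to the positive corneal SA, at 6 mm
    sa_reference_diameter_mm: 6.0
    sa_power_slope_um_per_D: 0.004
    abbe_number: 56
  neutral_monofocal:              # aberration-free reference lens
    family: neutral_monofocal
    add_power_D: 0.0
    zone_radius_mm: 0.0
    transition_width_mm: 0.0
    sa_coefficient_um: 0.0
    sa_reference_diameter_mm: 6.0
    sa_power_slope_um_per_D: 0.0
    abbe_number: 50
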