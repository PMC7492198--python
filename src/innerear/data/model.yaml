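# Model constants: lumped acoustic impedances (SI acoustic units) and
# anatomical geometry of the inner-ear network.
#
# Impedance coefficients evaluate as  Z(w) = jw*mass + resistance + stiffness/(jw)
# with mass in kg*m^-4, resistance in Pa*s*m^-3, stiffness in Pa*m^-3.
version: 1

fluid:
  density: 1000.0        # kg*m^-3, perilymph/CSF treated as water
  viscosity: 1.0e-3      # Pa*s

impedances:
  # middle ear seen from inside the OW: ossicle mass, damping, annular-ligament
  # stiffness; stiffness-dominated below its ~2 kHz resonance (Q ~ 1.6)
  Z_ME:   {mass: 4.4e+5, resistance: 1.2e+10, stiffness: 8.1e+13}
  Z_V:    {mass: 2.43e+5}                                           # half the vestibule fluid mass
  Z_SV:   {mass: 2.45e+5}                                           # half the scala-vestibuli mass
  Z_SVD:  {mass: 2.86e+7}                                           # scala-vestibuli duct
  Z_STD:  {mass: 2.14e+7}                                           # scala-tympani duct
  Z_C:    {mass: 1.002e+6, resistance: 1.0e+10}                     # basilar membrane + M_SV/2 + M_ST/2
  Z_RW:   {mass: 4.59e+5, resistance: 5.0e+8, stiffness: 7.0e+12}   # round window + remaining ST mass
  Z_H:                                                              # helicotrema, two branches in parallel
    parallel:
      - {mass: 1.7e+7, resistance: 2.0e+8}
      - {resistance: 2.2e+9, stiffness: 1.59e+12}

# Reference lumped values used only as cross-checks against the geometric
# constructions of the pathology-parameterized elements.
cross_checks:
  Z_VA:  {mass: 5.68e+7, resistance: 1.27e+10}
  Z_SSC: {mass_const: 2.83e+6, resistance_const: 3.9e+7}

geometry:
  cochlea:
    turns: 2.5
    n_sections: 180
    outer_radius_base_mm: 5.0
    outer_radius_apex_mm: 1.6
    # half-elliptic scala cross-sections, linear base -> apex taper
    scala_vestibuli: {width_base_mm: 1.8, height_base_mm: 1.2,
                      width_apex_mm: 1.6, height_apex_mm: 0.6}
    scala_tympani:   {width_base_mm: 2.5, height_base_mm: 1.4,
                      width_apex_mm: 1.6, height_apex_mm: 0.6}
  vestibule:
    length_mm: 5.8
    radius_a_mm: 1.55
    radius_b_mm: 2.45
    # axial separation of the oval window from the round window / cochlear
    # base along the model axis; the vestibule extends from the OW away
    # from the cochlea toward the canal and aqueduct openings
    window_offset_mm: 3.0
  stapes_footplate_area_mm2: 3.85
  vestibular_aqueduct:
    tube: {length_mm: 2.3, diameter_mm: 0.3}
    horn: {length_mm: 5.7, end_radius_a_mm: 3.25, end_radius_b_mm: 0.27}
    step_mm: 0.1
  cochlear_aqueduct:
    length_mm: 10.0
    diameter_mm: 0.15
  semicircular_canal:
    duct_length_mm: 6.0        # each of the two limbs, vestibule/crus to mid-canal
    area_near_mm2: 2.0         # cross-section near vestibule and common crus
    area_mid_mm2: 1.0          # cross-section at mid-canal (dehiscence site)
    hole_length_mm: 1.0        # bone thickness pierced by the dehiscence
    hole_aspect: 2.0           # dehiscence ellipse, semi-major = aspect * semi-minor

wave:
  speed_m_s: 300.0             # longitudinal bone-wave speed, configurable 100-1000
  direction: [1.0, 0.0]        # unit vector in the model plane
  acceleration_m_s2: 1.0       # common bone acceleration amplitude

grid:
  n: 120
  f_min_hz: 100.0
  f_max_hz: 10000.0
  required_hz: [100.0, 125.0, 250.0, 300.0, 500.0, 1000.0]
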