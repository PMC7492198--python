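# Stand-in excitation spectra for the literature-derived drives.
#
# The excitation spectra of the real ear (middle-ear transfer, ossicle-inertia
# stapes motion, ear-canal BC pressure, intracranial pressure) are known only
# from measurement studies whose data are not reproducible here; every
# reported output of this package is
# a ratio or change quantity that cancels the absolute source scale, or a
# power-summed total evaluated where a single contributor dominates.  The
# curves below are therefore smooth log-log piecewise-linear shapes with the
# qualitative features the literature describes, not digitized data.
#
# Each curve: breakpoints over log-frequency, magnitude in dB re an arbitrary
# reference, phase in degrees, linearly interpolated in log10(f).
version: 1

curves:
  # stapes velocity per Pa at the tympanic membrane, loaded middle ear (AC drive)
  middle_ear_transfer:
    freq_hz:  [100, 500, 1000, 2000, 10000]
    mag_db:   [0, 0, -2, -6, -20]
    phase_deg: [0, -10, -30, -60, -150]
  # stapes velocity per unit skull acceleration, ossicle-inertia pathway;
  # band-pass around the 1-2 kHz middle-ear resonance
  me_inertia:
    freq_hz:  [100, 400, 1500, 4000, 10000]
    mag_db:   [-35, -14, 0, -12, -24]
    phase_deg: [90, 60, 0, -60, -90]
  # ear-canal sound pressure per unit skull acceleration, open ear
  ear_canal:
    freq_hz:  [100, 1000, 10000]
    mag_db:   [0, -4, -14]
    phase_deg: [0, -20, -90]
  # intracranial (CSF) sound pressure per unit skull acceleration;
  # usable for absolute contribution plots only at >= 250 Hz
  csf_pressure:
    freq_hz:  [100, 250, 1000, 10000]
    mag_db:   [0, 0, -3, -12]
    phase_deg: [0, 0, -30, -120]
    min_valid_hz: 250.0

# Calibration of the stand-in contributors against the wave-derived fluid
# inertia in the healthy ear: each entry pins the contributor's BM flow,
# in dB relative to the fluid-inertia BM flow, at a reference frequency.
# me_inertia is pinned at its own spectral peak (near its 1-2 kHz resonance).
calibration:
  me_inertia:   {offset_db: -2.0, at: peak}
  compression:  {offset_db: -10.0, at: 500.0}
  ear_canal:    {offset_db: -15.0, at: 500.0}
  # anchored at the lowest frequency where the CSF curve is valid; the
  # pathway rolls off steeply with frequency (aqueduct mass), so a
  # higher-frequency anchor would let it overtake fluid inertia at the
  # bottom of the grid
  csf_pressure: {offset_db: -10.0, at: 250.0}
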