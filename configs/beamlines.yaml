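# Beamline presets for the three serial data collections compared in the
# study.  Photon counts follow from linear ring-current scaling at ID29;
# the XFEL rows book-keep the measured per-pulse photon numbers directly.
# Diffraction-weighted doses are external inputs (never recomputed here).
id29-feb2024:
  flux_at_ref: 1.6e15        # photons/s at 200 mA, pinhole-cleaned focus
  ref_current: 200.0         # mA
  current: 68.0              # mA
  exposure: 90.0e-6          # s
  photon_energy: 11.56       # keV
  beam_area: 8.0             # µm² (2 x 4 µm focus)
  attenuation_transmission: 1.0
  rate_hz: 231.25
  diffraction_weighted_dose_mgy: 0.88

cristallina-jun2023:
  photons_per_pulse: 5.44e10
  photon_energy: 12.04       # keV
  beam_area: 25.0            # µm² (~5 x 5 µm FWHM)
  exposure: 30.0e-15         # s (assumed pulse length)
  rate_hz: 100.0
  diffraction_weighted_dose_mgy: 0.20

cristallina-sep2023:
  photons_per_pulse: 6.22e10
  photon_energy: 12.04       # keV
  beam_area: 36.0            # µm² (~6 x 6 µm FWHM)
  exposure: 25.0e-15         # s (measured pulse length)
  rate_hz: 100.0
  diffraction_weighted_dose_mgy: 0.18
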