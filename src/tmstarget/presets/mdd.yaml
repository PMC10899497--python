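# Left-DLPFC search space for targeting the depression pathological network.
# ROI sphere centers: BA9, BA46, Beam-F3 and the "5-cm" site (MNI mm).
name: mdd
search_space:
  nz_range: [0.15, 0.43]
  al_range: [0.27, 0.43]
  step: 0.01
roi_centers_mni:
  - [-36, 39, 43]
  - [-44, 40, 29]
  - [-37, 26, 49]
  - [-41, 16, 54]
roi_radius_mm: 20.0
orientation_deg: 45.0
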