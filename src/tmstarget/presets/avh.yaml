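# Left TPJ / Wernicke search space for targeting the auditory-verbal-
# hallucination pathological network.  ROI sphere centers in MNI mm.
name: avh
search_space:
  nz_range: [0.52, 0.80]
  al_range: [0.10, 0.26]
  step: 0.01
roi_centers_mni:
  - [-57, -49, 28]
  - [-65, -41, 9]
roi_radius_mm: 20.0
orientation_deg: 23.0
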