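# Full synthetic-cohort verification run.
seed: 1
n_subjects: 7
do_registration: true
policy:
  eer_threshold: 1.4
  cnr_threshold: 3.5
  k_sd: 3
  min_island_diameter_mm: 3
  segment_radius_mm: 10
  shell_mm: 12
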