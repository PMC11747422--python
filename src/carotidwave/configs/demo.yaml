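# Demo pipeline configuration: a study-scale longitudinal cohort
# (6 mice per genotype per sex, imaged at 50/75/125 days on both carotids)
# run through the full chain: waveform synthesis, M-mode/Doppler rendering,
# trace extraction, cycle averaging, hemodynamic metrics and statistics.
seed: 0
outdir: runs/demo
log_level: INFO

stages:
  simulate: true
  extract: true
  analyze: true
  stats: true
  figures: true

cohort:
  n_per_group: 6
  ages: [50, 75, 125]
  dropout: true             # two male dcr mice die before the final age
  arrhythmia_fraction: 0.25 # expected 6 of 24 mice with arrhythmic beats

waveform:
  n_cycles: 10
  fs: 1000.0
  noise_sd: 0.02            # fraction of the pulsatile amplitude
  arrhythmia_jitter: 0.15   # heavy-tailed RR jitter scale for flagged mice
  save_waveforms: false

render:
  pixel_pitch_mm: 0.01
  v_bin_mm_s: 2.0
  speckle_weight: 0.5
  noise_floor: 0.05
  save_images: false

extraction: {}

cycles:
  n_samples: 256
  max_rr_deviation: 0.2

stats:
  alpha: 0.05
  stratified: false
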