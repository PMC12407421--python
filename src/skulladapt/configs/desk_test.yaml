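# Desk-scale profile: small forge, coarse view sphere, tiny backbone.
# Finishes the full six-regime comparison in minutes on one CPU.
seed: 0
output_dir: skulladapt_out

forge:
  n_species: 4
  specimens_per_species: 6
  photo_specimens_per_species: 10
  drop: []
  standard_length: 1.0
  target_faces: 600
  subdivisions: 3

viewsphere:
  yaw_step: 90.0
  ring_pitches: [0.0, 30.0, -30.0]
  include_poles: false
  distance: 2.5

render:
  resolution: 64
  light_direction: [0.4, 0.3, 0.85]
  ambient: 0.25
  diffuse: 0.7
  background_level: 0.12
  fov_degrees: 35.0

photo_domain:
  background_marking_density: 1.5
  brightness_jitter_sd: 0.12
  color_cast_strength: 0.08
  blur_sigma: 0.6
  noise_sd: 0.04
  distance_jitter_sd: 0.05
  session_confound: false

datapipe:
  test_fraction: 0.2
  subset_fraction: 0.25
  resize_side: 48
  augment:
    translate_frac: 0.05
    hflip_prob: 0.5
    brightness_range: 0.1
    contrast_range: 0.1
    saturation_range: 0.1
    hue_range: 0.02

training:
  backbone:
    kind: tiny
    input_side: 48
    hidden_dim: 64
  learning_rate: 0.002
  max_epochs: 35
  patience: 10
  batch_size: 32
  mmd:
    weight: 1.0
  regimes: [baseline, photo_baseline, photo_subset, mmd, finetune, supplemented]

evaluation:
  gradcam_sample: 40
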