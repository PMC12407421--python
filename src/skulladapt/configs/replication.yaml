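# Replication-scale profile: 16 species x 30 specimens (one dropped from the
# last species), the 92-pose view sphere, 720 px renders scaled to 224 px,
# and the VGG19-like backbone.  This profile reproduces the dataset geometry
# of a full study (44,068 render tasks; 35,328:8,740 synthetic train:test
# images) and is sized for a workstation, not for the test suite.
seed: 0
output_dir: skulladapt_replication

forge:
  n_species: 16
  specimens_per_species: 30
  photo_specimens_per_species: 10
  drop: [[15, 1]]        # emulates one corrupted scan
  standard_length: 1.0
  target_faces: 2000
  subdivisions: 4

viewsphere:
  yaw_step: 20.0
  ring_pitches: [0.0, 30.0, -30.0, 60.0, -60.0]
  include_poles: true
  distance: 3.0

render:
  resolution: 720
  light_direction: [0.4, 0.3, 0.85]
  ambient: 0.25
  diffuse: 0.7
  background_level: 0.12
  fov_degrees: 35.0

photo_domain:
  background_marking_density: 1.0
  brightness_jitter_sd: 0.12
  color_cast_strength: 0.08
  blur_sigma: 1.5
  noise_sd: 0.04
  distance_jitter_sd: 0.05
  session_confound: true

datapipe:
  test_fraction: 0.2
  subset_fraction: 0.25
  resize_side: 224
  augment:
    translate_frac: 0.1
    hflip_prob: 0.5
    brightness_range: 0.2
    contrast_range: 0.2
    saturation_range: 0.2
    hue_range: 0.05

training:
  backbone:
    kind: vgg19_like
    input_side: 224
    hidden_dim: 256
  learning_rate: 0.0005
  max_epochs: 100
  patience: 15
  batch_size: 32
  mmd:
    weight: 1.0
  regimes: [baseline, photo_baseline, photo_subset, mmd, finetune, supplemented]

evaluation:
  gradcam_sample: 100
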