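# cross-section spot counting in a flipped-gel dendrite
workflow: flipexm
trim: 12
step: 3
crosstalk_method: pooled_mean
scene:
  scene_kind: dendrite
  orientation: flipped
  dendrite_diameter: 1.0
  dendrite_length: 4.0
  n_microtubules: 30
  fraction_acetylated: 0.7333333333333333
  fraction_tyrosinated: 0.23333333333333334
  fraction_other: 0.03333333333333333
  radial_bias: 0.3
  true_alpha: 0.45
  true_beta: 0.60
  noise_model: poisson
  background_level: 5.0
  filament_photons: 40000.0
  psf_sigma_lateral: 0.10
  psf_sigma_axial: 0.30
  voxel_size: [0.06, 0.06, 0.06]
  expansion_factor: 4.15
  seed: 5
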