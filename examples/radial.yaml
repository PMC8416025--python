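# radial density profiles of a core/shell dendrite plus decomposition
workflow: radial
trim: 12
step: 8
boundary:
  reference_channel: total
scene:
  scene_kind: dendrite
  orientation: flipped
  dendrite_diameter: 1.2
  dendrite_length: 4.0
  n_microtubules: 60
  fraction_acetylated: 0.5
  fraction_tyrosinated: 0.5
  fraction_other: 0.0
  radial_bias: 1.0
  true_alpha: 0.45
  true_beta: 0.60
  noise_model: poisson
  background_level: 5.0
  filament_photons: 40000.0
  psf_sigma_lateral: 0.10
  psf_sigma_axial: 0.30
  voxel_size: [0.06, 0.06, 0.06]
  expansion_factor: 4.15
  seed: 3
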