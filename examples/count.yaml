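# soma-calibrated dendrite counting: calibrate on the soma scene, then
# count microtubules in a simulated dendrite of the same imaging setup
workflow: soma_sted
scene:
  scene_kind: soma_sheet
  n_microtubules: 200
  sheet_size: 25.0
  bundle_fraction: 0.2
  true_alpha: 0.53
  true_beta: 0.45
  fraction_acetylated: 0.5
  fraction_tyrosinated: 0.5
  fraction_other: 0.0
  noise_model: poisson
  background_level: 10.0
  filament_photons: 20000.0
  psf_sigma_lateral: 0.03
  psf_sigma_axial: 0.25
  voxel_size: [0.04, 0.04, 0.15]
  seed: 7
dendrite_scene:
  scene_kind: dendrite
  dendrite_diameter: 1.954
  dendrite_length: 6.0
  n_microtubules: 159
  fraction_acetylated: 0.72
  fraction_tyrosinated: 0.26
  fraction_other: 0.02
  radial_bias: 0.3
  true_alpha: 0.53
  true_beta: 0.45
  noise_model: poisson
  background_level: 10.0
  filament_photons: 20000.0
  psf_sigma_lateral: 0.03
  psf_sigma_axial: 0.25
  voxel_size: [0.04, 0.04, 0.15]
  seed: 21
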