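# sparse soma sheet with two-filament bundles and modification crosstalk
workflow: simulate
scene:
  scene_kind: soma_sheet
  n_microtubules: 120
  sheet_size: 18.0
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
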