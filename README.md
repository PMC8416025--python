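# mtquant

Quantification of dense microtubule arrays in multi-channel fluorescence
z-stacks (total / tyrosinated / acetylated tubulin). The package implements
the full analysis chain:

- **simgen** — synthetic microscopy scenes with ground truth: sparse soma
  sheets (with two-filament bundles), dendrites with core/shell-biased
  microtubule subtypes, circumferential flipped-gel dendrites; anisotropic
  Gaussian PSF at two sample orientations, expansion-factor scaling,
  Poisson/Gaussian noise.
- **stackio / rois** — OME-TIFF stack I/O with voxel-size metadata,
  ImageJ `.roi`/`.zip` and JSON ROIs, channel registration by projection
  phase correlation, dendrite straightening + YZ reslicing.
- **filaments** — soma-stage calibration: curvilinear segment detection
  (pluggable; imported ROIs are first-class), dual-width (6 px / 13 px)
  background-corrected intensities in all channels, two-Gaussian
  single-filament intensity fit (doublet component is the analytic
  self-convolution), singles filtering at `I + sigma`, and crosstalk
  coefficients alpha / beta.
- **counting** — dendrite band measurement, conversion to microtubule
  numbers via the single-filament intensity, and exact linear unmixing of
  tyrosinated / acetylated / other counts.
- **radial** — per-slice dendrite boundary (rectangle scan, multi-threshold
  tracking, 8-anchor periodic spline; convex-hull alternative), radial
  density by iterative Euclidean-distance-map contour erosion, and
  closed-form two-component decomposition of the total density.
- **flipexm** — cross-section spot detection in YZ slices, roundness and
  MLE-area filters, per-channel intensity calibration, three crosstalk
  estimators, per-slice and per-dendrite counting.
- **longprofile** — perpendicular Gaussian fits along a dendrite,
  first-5-µm normalization, spike exclusion, 2 µm smoothing, FWHM.
- **pipeline / cli** — config-driven workflows with deterministic seeding.

## CLI

All verbs live under a single `mtquant` entry point:

```bash
# render a synthetic scene (OME-TIFF + ground-truth JSON/CSV)
mtquant simulate --config examples/scene.yaml --out out/

# soma-stage calibration on a stack
mtquant filaments --stack soma.ome.tif --out out/

# soma-calibrated dendrite counting on a simulated pair of scenes
mtquant count --config examples/count.yaml --out out/

# radial profiles + decomposition; channel registration; straightening
mtquant radial --config examples/radial.yaml --out out/
mtquant register --stack stack.ome.tif --out registered.ome.tif
mtquant straighten --stack stack.ome.tif --roi path.roi --half-width 20 --out yz.tif
mtquant decompose total.csv tyr.csv ac.csv

# FlipExM counting; longitudinal profile
mtquant flipexm --config examples/flipexm.yaml --out out/
mtquant profile --stack stack.ome.tif --roi dendrite.roi --out profile.csv
```

A config file is a YAML/JSON mapping with a `workflow` key
(`simulate | soma_sted | flipexm | radial`), a `scene` mapping holding
`SceneSpec` fields (see `mtquant.simgen.SceneSpec`), and optional stage
parameter overrides. The same config plus seed reproduces byte-identical
outputs.

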