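# End-to-end synthetic run: paired DWI/FLAIR phantoms with a shrinking lesion.
schema: 1
phantom:
  pre:
    grid_shape: [96, 96, 48]
    spacing_mm: [1.0, 1.0, 2.0]        # in-plane pixel spacing, slice thickness
    lesion_center_mm: [48.0, 48.0, 48.0]
    lesion_semiaxes_mm: [12.0, 10.0, 8.0]
    lesion_intensity: 200.0
    background_intensity: 100.0
    noise_sd: 5.0
  post:                                 # grid geometry inherited from pre
    lesion_center_mm: [48.0, 48.0, 48.0]
    lesion_semiaxes_mm: [10.0, 8.0, 7.0]
    lesion_intensity: 200.0
    background_intensity: 100.0
    noise_sd: 5.0
segmentation:
  rel_threshold: 0.20
  connectivity: 8
  mode: 2d_propagate
coil:
  current_A: 240.0
  standoff_mm: 2.0
  # curvature_radius_mm: 90.0          # uncomment for the head-curvature warp
dose:
  threshold_mT: 1.0
output_dir: out
rng_seed: 7
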