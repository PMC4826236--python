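# Demo run: two simulated arms (control vs cisplatin-like treated chromatin),
# five coverslips each; segment nuclei, profile texture, compare the arms.
seed: 1
output_dir: runs/demo
stages: [simulate, segment, texture, compare]
simulate:
  kind: texture
  n_samples_per_arm: 5
  arms:
    control: {texture_regime: control, clumpiness: 0.0}
    treated: {texture_regime: treated, clumpiness: 0.4}
  spec: {height: 256, width: 256, n_nuclei: 12}
glcm: {levels: 32, distance: 1, angles: [0, 45, 90, 135], symmetric: true}
segmentation: {smoothing_sigma: 2.0, min_area: 100}
compare: {method: mann_whitney}
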