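# Synthetic two-group study: 2 x 3 mice, 4 images each, rendered scenes.
outdir: results/study
seed: 20260924
log_level: INFO
simulation:
  mice_per_group: 3
  images_per_mouse: 4
  scene:
    shape: [384, 384]
    n_arterioles: 3
    n_capillaries: 6
    n_intramural: 5
    n_extramural: 20
    noise_sd: 2.0
    poisson_scale: 0.5
segmentation: {}
detection: {}
statistics:
  n_restarts: 1
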