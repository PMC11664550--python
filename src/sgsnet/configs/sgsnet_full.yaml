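# Frozen full-size configuration (5 classes, 640x640 input).
# Stage depths/expansions and neck/head widths calibrated so the analytic
# audit matches the published complexity budget (~5.86 M parameters,
# ~14.7 GFLOPs at 640x640); the backbone counts 16 convolution layers
# (stem + 5 inverted-bottleneck blocks x 3 convs).
backbone:
  stem_width: 64
  stages:
    - {width: 128, depth: 1, expansion: 4.0, dw_kernel: 3}
    - {width: 256, depth: 1, expansion: 2.0, dw_kernel: 3}
    - {width: 512, depth: 2, expansion: 2.0, repeat_expansion: 2.0, dw_kernel: 5}
    - {width: 1024, depth: 1, expansion: 1.5, dw_kernel: 5}
neck:
  p3_channels: 128
  p4_channels: 160
  p5_channels: 192
  sppelan_hidden: 128
  elan_hidden_frac: 0.5
  heads: 4
  window: 7
  dysample_groups: 4
head_hidden: 112
n_classes: 5
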