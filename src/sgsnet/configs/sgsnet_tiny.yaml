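# Desk-scale preset used by the tests and training demonstrations.
backbone:
  stem_width: 8
  stages:
    - {width: 16, depth: 1, expansion: 2.0, dw_kernel: 3}
    - {width: 32, depth: 1, expansion: 2.0, dw_kernel: 3}
    - {width: 64, depth: 1, expansion: 2.0, dw_kernel: 5}
    - {width: 128, depth: 1, expansion: 2.0, dw_kernel: 5}
neck:
  p3_channels: 32
  p4_channels: 48
  p5_channels: 64
  sppelan_hidden: 32
  elan_hidden_frac: 0.5
  heads: 4
  window: 4
  dysample_groups: 4
head_hidden: 32
n_classes: 5
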