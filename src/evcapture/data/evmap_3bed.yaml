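# 3-bed affinity-capture chip (COC, hot-embossed, circular micropillars).
# The three serial beds are represented as one effective bed spanning the
# full 122 mm serial flow path.
name: evmap_3bed
arrangement: serial
beds:
  - length_mm: 122
    width_mm: 1.7
    depth_um: 90
    pillar_shape: circular
    pillar_size_um: 100
    pillar_spacing_um: 15
    n_pillars: 15202
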