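# 7-bed z-configuration chip (COP, injection-molded, diamond micropillars).
# 1,475,712 pillars total across 7 identical parallel beds.
name: evmap_7bed
arrangement: parallel
beds:
  - &bed
    length_mm: 23
    width_mm: 3.6
    depth_um: 50
    pillar_shape: diamond
    pillar_size_um: 10
    pillar_spacing_um: 10
    n_pillars: 210816
  - *bed
  - *bed
  - *bed
  - *bed
  - *bed
  - *bed
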