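# Immune-cell marker genes curated from the nCounter PanCancer Immune
# Profiling Panel whitepaper, restricted to probes analyzed by the pipeline.
nk:
  - GTF3C1
  - ZNF205
  - GZMB
  - IL21R
b_cell:
  - CD19
  - MS4A1
  - CD22
  - CD79A
  - CD79B
  - TNFRSF17
t_cell:
  - CD3D
  - CD3E
  - CD3G
  - CD4
  - CD8A
  - CD8B
apc:
  - CD68
  - CD163
  - CCL13
  - CD209
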