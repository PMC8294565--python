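grid:
  Lx: 4.0
  Ly: 4.0
  h: 0.05
kind: spatial
parameters:
  eta: 0.65
probes:
- - 1.0
  - 1.0
releases:
  mode: initial-only
  stations:
  - - 0.0
    - 0.0
years: 35
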