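name: 4x4
colors:
  - "teal navy gold gray"
  - "brown lime coral olive"
  - "purple orange cyan pink"
  - "red green blue yellow"
east_doors:
  - "1 1 1"
  - "1 1 1"
  - "1 1 1"
  - "1 1 1"
north_doors:
  - "1 1 1 1"
  - "1 1 1 1"
  - "1 1 1 1"
starts:
  - [0, 0]
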