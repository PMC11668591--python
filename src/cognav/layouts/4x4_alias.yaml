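name: 4x4_alias
colors:
  - "green blue red yellow"
  - "purple cyan green pink"
  - "cyan red yellow blue"
  - "red green blue purple"
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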