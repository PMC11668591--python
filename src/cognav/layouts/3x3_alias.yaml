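name: 3x3_alias
colors:
  - "green blue green"
  - "red yellow blue"
  - "green red yellow"
east_doors:
  - "0 1"
  - "0 0"
  - "1 1"
north_doors:
  - "1 0 1"
  - "1 1 1"
starts:
  - [0, 0]
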