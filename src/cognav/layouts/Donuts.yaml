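name: Donuts
goal_color: pink
colors:
  - "gold teal lime pink navy"
  - "orange . . . brown"
  - "purple . . . gray"
  - "red green blue yellow cyan"
east_doors:
  - "1 1 1 1"
  - "0 0 0 0"
  - "0 0 0 0"
  - "1 1 1 1"
north_doors:
  - "1 0 0 0 1"
  - "1 0 0 0 1"
  - "1 0 0 0 1"
starts:
  - [0, 0]
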