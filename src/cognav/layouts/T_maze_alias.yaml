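name: T_maze_alias
goal_color: red
colors:
  - "red blue green blue red"
  - ". . yellow . ."
  - ". . purple . ."
  - ". . blue . ."
east_doors:
  - "1 1 1 1"
  - "0 0 0 0"
  - "0 0 0 0"
  - "0 0 0 0"
north_doors:
  - "0 0 1 0 0"
  - "0 0 1 0 0"
  - "0 0 1 0 0"
starts:
  - [0, 3]
  - [4, 3]
  - [2, 0]
  - [2, 3]
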