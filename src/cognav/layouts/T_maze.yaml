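name: T_maze
colors:
  - "red green blue yellow purple"
  - ". . orange . ."
  - ". . cyan . ."
  - ". . pink . ."
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
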