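name: Tolman
goal_color: red
colors:
  - ". . . red teal lime pink"
  - ". . . gold . . cyan"
  - ". navy plum olive . . green"
  - ". teal . green . . ivory"
  - ". lime . blue . . blue"
  - ". pink cyan gray brown coral mint"
  - ". . . tan . . ."
east_doors:
  - "0 0 0 1 1 1"
  - "0 0 0 0 0 0"
  - "0 1 1 0 0 0"
  - "0 0 0 0 0 0"
  - "0 0 0 0 0 0"
  - "0 1 1 1 1 1"
  - "0 0 0 0 0 0"
north_doors:
  - "0 0 0 1 0 0 1"
  - "0 0 0 1 0 0 1"
  - "0 1 0 1 0 0 1"
  - "0 1 0 1 0 0 1"
  - "0 1 0 1 0 0 1"
  - "0 0 0 1 0 0 0"
starts:
  - [3, 0]
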