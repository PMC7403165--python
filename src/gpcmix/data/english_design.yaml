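language_mode: english_style
conditions:
- CS_O+CS_B+
- CS_O-CS_B+
- CS_O+CS_B-
- CS_O-CS_B-
response_categories:
- ae
- open_o
- long_o
rule_types:
- simpleGPC
- CS_O
- CS_B
items_per_condition:
  CS_O+CS_B+: 16
  CS_O-CS_B+: 16
  CS_O+CS_B-: 16
  CS_O-CS_B-: 16
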