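language_mode: german_style
conditions:
- SR+CS_B+
- SR-CS_B+
- SR+CS_B-
- SR-CS_B-
response_categories:
- short
- long
rule_types:
- simpleGPC
- SR
- CS_B
items_per_condition:
  SR+CS_B+: 16
  SR-CS_B+: 16
  SR+CS_B-: 16
  SR-CS_B-: 16
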