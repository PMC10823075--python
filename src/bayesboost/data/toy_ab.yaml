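nodes:
- name: A
  levels:
  - '0'
  - '1'
  parents: []
  table:
  - - 0.7
    - 0.3
- name: B
  levels:
  - '0'
  - '1'
  parents:
  - A
  table:
  - - 0.8
    - 0.2
  - - 0.2
    - 0.8
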