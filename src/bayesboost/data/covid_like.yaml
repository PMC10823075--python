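nodes:
- name: gender
  levels:
  - F
  - M
  parents: []
  table:
  - - 0.52
    - 0.48
- name: region
  levels:
  - London
  - South Central
  - North West
  - North East
  - Yorkshire
  - East Midlands
  - West Midlands
  - East of England
  - South East
  - South West
  parents: []
  table:
  - - 0.16
    - 0.12
    - 0.09
    - 0.09
    - 0.09
    - 0.09
    - 0.09
    - 0.09
    - 0.09
    - 0.09
- name: age
  levels:
  - '[18,35)'
  - '[35,50)'
  - '[50,65)'
  - '[65,80)'
  - '[80,95)'
  parents: []
  table:
  - - 0.28
    - 0.26
    - 0.22
    - 0.16
    - 0.08
- name: covid_diagnosis
  levels:
  - '0'
  - '1'
  parents:
  - gender
  - age
  table:
  - - 0.9308615796566532
    - 0.06913842034334682
  - - 0.9046505351008906
    - 0.09534946489910949
  - - 0.8698915256370021
    - 0.13010847436299783
  - - 0.8249137318359603
    - 0.17508626816403977
  - - 0.7685247834990176
    - 0.23147521650098232
  - - 0.9205614508160216
    - 0.07943854918397836
  - - 0.8909031788043871
    - 0.10909682119561294
  - - 0.8519528019683106
    - 0.14804719803168945
  - - 0.8021838885585818
    - 0.1978161114414182
  - - 0.7407748991821541
    - 0.25922510081784594
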