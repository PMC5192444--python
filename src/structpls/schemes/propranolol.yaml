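# Three-block mixed coding: categorical strain block on a 0/6 scale plus two
# ordinal columns, scaled so a worst-case error is comparable across blocks.
# Time codes 0/1/6 mirror the real sampling times 0, 10 and 60 min.
blocks:
- name: strain
  type: categorical
  levels: [S1, S2, S3]
  codes: [0, 6]
- name: dosage
  type: ordinal
  levels: [D0, D1, D2, D3]
  codes: [0, 2, 4, 6]
- name: time
  type: ordinal
  levels: [T0, T1, T2]
  codes: [0, 1, 6]
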