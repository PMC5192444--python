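# Variant of the propranolol scheme with evenly spaced time codes.
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
  codes: [0, 3, 6]
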