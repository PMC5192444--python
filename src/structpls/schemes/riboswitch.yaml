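# Two-factor full-factorial coding: 5 E. coli strains x 4 inducer conditions,
# both blocks as 0/1 one-of-k sub-matrices (Y width 9).
blocks:
- name: strain
  type: categorical
  levels: [wild-type, PET, EGFP, iL3EGFP, iL3PET]
  codes: [0, 1]
- name: inducer
  type: categorical
  levels: [no_inducer, IPTG, IPTG+PPDA, PPDA]
  codes: [0, 1]
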