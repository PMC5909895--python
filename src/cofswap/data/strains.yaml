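# Measured exponential-phase physiology on acetate (batch cultures) and the
# genetic edits of each strain. mu in 1/h, qac in mmol/gDW/h.
strains:
  - strain: wild_type
    mu: 0.196
    qac: 7.88
    swap_fraction: 0.0
    knockouts: []
  - strain: pntab_ko
    mu: 0.191
    qac: 7.6
    swap_fraction: 0.0
    knockouts: [THD2pp]
  - strain: icd_nad
    mu: 0.135
    qac: 8.0
    swap_fraction: 1.0
    knockouts: []
  - strain: icd_nad_pntab_ko
    mu: 0.1203
    qac: 7.0
    swap_fraction: 1.0
    knockouts: [THD2pp]
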