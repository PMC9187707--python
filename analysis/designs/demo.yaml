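# Small demonstration design: 2 subjects x 2 regions x 1 layer x 6 sites,
# compact fields.  Runs end-to-end in well under a minute.
regions: [PFC, A1]
subjects_per_species: 2
sites_per_layer: 6
stack:
  nx: 48
  ny: 48
  n_puncta: {vglut1: 15, vgat: 15, lipofuscin: 3}
  decoy_fractions: {overlap: 0.1, lipofuscin_overlap: 0.3}
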