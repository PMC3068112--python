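# Small bundled configuration: a desk-scale version of the two-family study
# design (sizes chosen so the whole pipeline completes in well under five
# minutes on one CPU).
seed: 1
out: results/small
populations:
  P: {n_progeny: 100, years: [2004, 2005]}
  D: {n_progeny: 140, years: [2006, 2007]}
map:
  n_groups: 3
  group_length: 100.0
  markers_per_group: 20
  class_mix: [0.3, 0.3, 0.4]
marker_keep_frac: 0.9
missing_rate: 0.005
scan:
  step: 2.0
  n_perm: 300
  alpha: 0.05
  reporting: false
coloc:
  n: 500
  drop: 1
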