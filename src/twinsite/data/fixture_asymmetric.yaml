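description: 'Synthetic fixture: 17-parameter free-energy set (kT at 298.15 K) with
  asymmetric mutant kinetics; found by constrained search within the prior box. Not
  experimental data.'
seed: 20250927
parameters:
  barrier.bind_ATP_I: 23.769641
  barrier.bind_ADP_I: 23.691868
  barrier.bind_ATP_II: 18.188993
  barrier.bind_ADP_II: 23.337783
  barrier.conf_TT: 20.744231
  barrier.conf_TD: 33.347967
  barrier.conf_DT: 24.596661
  barrier.conf_DD: 30.044218
  barrier.hyd_I: 19.851744
  barrier.hyd_II: 27.891259
  dG.bind_ATP_I: -5.76644
  dG.bind_ADP_I: -10.09623
  dG.bind_ATP_II: -5.36184
  dG.bind_ADP_II: -23.460557
  dG.open_to_closed: 2.41134
  dG.ATP_to_ADP_closed_I: -6.518555
  dG.ATP_to_ADP_closed_II: -4.790801
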