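scenario:
  name: fig1E_sweep
  kind: sweep
  params:
    ga12_synthesis: 1.0
    k_ga12_ox: 1.0
    k_ga15_ox: 1.0
    k_ga24_ox: 1.0
    k_ga9_ox: 1.0
    ga_intermediate_turnover: 0.1
    ga4_turnover: 1.0
    ga4_gid1_on: 10.0
    ga4_gid1_off: 1.0
    ternary_decay: 1.0
    ga20ox_tx: 1.0
    ga20ox_K: 1.0
    ga20ox_n: 2.0
    ga20ox_mrna_decay: 1.0
    ga20ox_tl: 1.0
    ga20ox_decay: 0.5
    ga3ox_tx: 1.0
    ga3ox_K: 1.0
    ga3ox_n: 2.0
    ga3ox_mrna_decay: 1.0
    ga3ox_tl: 1.0
    ga3ox_decay: 0.5
    gid1_tx: 1.0
    gid1_K: 1.0
    gid1_n: 2.0
    gid1_mrna_decay: 1.0
    gid1_tl: 1.0
    gid1_decay: 0.5
    della_tx: 1.0
    della_K: 1.0
    della_n: 2.0
    della_mrna_decay: 1.0
    della_tl: 1.0
    della_decay: 0.1
    della_ga_decay: 10.0
    hacr_tx: 1.0
    hacr_tl: 1.0
    hacr_mrna_decay: 1.0
    hacr_protein_decay: 0.1
    hacr_ga_decay: 10.0
    hacr_repstr: 1.0
    hacr_rep_exponent: 1.0
  variant:
    variant: no_degron_cr
    target: GA20ox
  t_end: 200.0
  n_points: 401
  seed: 0
  axis_x:
    name: hacr_repstr
    values:
    - 0.01
    - 0.037275937203149395
    - 0.13894954943731375
    - 0.517947467923121
    - 1.9306977288832496
    - 7.196856730011514
    - 26.826957952797244
    - 100.0
    scale: log
  axis_y:
    name: hacr_protein_decay
    values:
    - 0.001
    - 0.0037275937203149396
    - 0.013894954943731375
    - 0.0517947467923121
    - 0.19306977288832497
    - 0.7196856730011514
    - 2.6826957952797246
    - 10.0
    scale: log
out_dir: out/fig1E_sweep
rtol: 1.0e-08
atol: 1.0e-10
ss_tol: 1.0e-08
t_max: 5000.0
seed: 0
verbosity: INFO
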