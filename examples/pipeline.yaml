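# Two simulated tissue groups analysed end to end:
#   tocky run --config examples/pipeline.yaml --out runs/demo --seed 1
seed: 1
min_n: 20
gate_quantile: 0.999
norm_quantile: 0.975
samples:
  - label: inflamed_1
    group: inflamed
    n_cells: 800
    mixture:
      - {program: persistent, weight: 0.7, onset_age: [50.0, 200.0]}
      - {program: new_onset, weight: 0.3, onset_age: [0.5, 4.0]}
  - label: inflamed_2
    group: inflamed
    n_cells: 800
    mixture:
      - {program: persistent, weight: 0.7, onset_age: [50.0, 200.0]}
      - {program: new_onset, weight: 0.3, onset_age: [0.5, 4.0]}
  - label: control_1
    group: control
    n_cells: 800
    mixture:
      - {program: arrested, args: {t_stop: 50.0}, weight: 0.8, onset_age: [100.0, 300.0]}
      - {program: persistent, weight: 0.2, onset_age: [100.0, 300.0]}
  - label: control_2
    group: control
    n_cells: 800
    mixture:
      - {program: arrested, args: {t_stop: 50.0}, weight: 0.8, onset_age: [100.0, 300.0]}
      - {program: persistent, weight: 0.2, onset_age: [100.0, 300.0]}
comparisons:
  - {metric: mean_angle, test: mann_whitney}
  - {metric: frac_Persistent, test: mann_whitney}
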