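# Demo configuration for `tds run-all`: a reduced simulated study that runs
# end-to-end in seconds. Thresholds are the pipeline defaults.
simulate: true
n_wt: 12
n_disease: 12
n_wt_test2: 10
n_disease_test2: 10
n_null: 200
n_treated: 6
seed: 11
drugs:
  - name: full_reversal
    rho: 1.0
    off_target_fraction: 0.05
  - name: inert
    rho: 0.0
    off_target_fraction: 0.0
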