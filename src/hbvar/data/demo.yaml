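# Demo end-to-end run: small Table-2-style synthetic cohort with the
# recorded-data error modes switched on.
outdir: demo_run
seed: 7
simulate:
  seed: 7            # overwritten by the pipeline's stage seed
  n_patients: 2000
  strata: table2
  error_rates:
    percent_unit_error: 0.002
    same_day_duplicate: 0.002
    implausible_high: 0.0001
    identical_run: 0.001
cleaning: {}
methods: [reml, crude, log]
subgroup_specs:
  - variable: diabetic_status
  - variable: sex
  - variable: n_measurements
    bin_edges: [4, 7, 11, 18, 1000]
mcid: 5.5
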