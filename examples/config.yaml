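# Example run configuration for `ihcsig run-all --config examples/config.yaml`
mode: synthetic          # synthetic | cell-tables | patient-table
seed: 1
n_patients: 293
threshold_policy: fixed  # fixed (published cutoffs) | estimate (median/scan)
applicability_mode: cohort_wide   # cohort_wide | restricted
missing_policy: zero     # zero (missing component -> 0) | exclude
horizons: [null, 60.0]   # ROC horizons in months; null = any follow-up
output_dir: scratch/yaml_run
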