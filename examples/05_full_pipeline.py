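"""One-call reproducible pipeline run: simulate -> subtype -> threshold ->
signature -> evaluate, with CSV stage outputs and a hashed JSON report.

Equivalent shell command:
    ihcsig run-all --config examples/config.yaml
"""

import json

from ihcsig import RunConfig, run_pipeline

config = RunConfig(
    mode="synthetic",
    seed=1,
    n_patients=293,
    threshold_policy="fixed",       # published cutoffs; "estimate" re-derives them
    applicability_mode="cohort_wide",
    output_dir="scratch/example_run",
)
report = run_pipeline(config)

print("stage outputs written to", config.output_dir)
print("report hash:", report["report_hash"][:16])
print("\nthresholds used:")
for m, t in report["thresholds"].items():
    print(f"  {m:<18} cutoff={t['cutoff']:>8.2f}  logrank p={t['logrank_p']}")
print("\nbinary signature stratum (score > 0 vs <= 0):")
print(json.dumps(report["signature"]["binary"], indent=2))
# The report is deterministic given (config, seed): rerunning with the same
# inputs reproduces the identical hash, which is how runs are audited.
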