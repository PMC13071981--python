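"""Generate a synthetic breast-cancer cohort and inspect its structure.

The generator draws a St Gallen subtype for each patient at the published
prevalences, six IHC biomarker readouts from subtype-dependent truncated
normals, and a relapse time from an exponential proportional-hazards model
in which biomarker-high status is protective.
"""

from ihcsig import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_patients=293, seed=1))

print(cohort[["patient_id", "subtype_true", "TOP2A", "PTEN", "time_months", "event"]].head())
print()
print("subtype counts:")
print(cohort["subtype_true"].value_counts())
print(f"\nrelapse events: {cohort['event'].sum()} of {len(cohort)} "
      f"({100 * cohort['event'].mean():.1f}% over a 120-month window)")
# Each row is one patient; TOP2A is % positive nuclei (0-100), PTEN an
# H-score (0-300). event=1 marks relapse before administrative censoring.
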