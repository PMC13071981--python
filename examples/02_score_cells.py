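"""From a per-cell digital-pathology export to per-patient biomarker scores.

A tissue-microarray core is a table of detected cells with DAB optical
densities per subcellular compartment. Scoring bins each density into an
ordinal intensity (0-3), applies core QC (>= 100 tumour cells), computes
percent-positive or H-scores over tumour cells only, and averages a
patient's qc-passing triplicate cores.
"""

import pandas as pd

from ihcsig import default_panel, h_score, patient_scores, score_cells, simulate_cells

panel = default_panel()

# three cores for one patient: two good, one sparse (fails QC)
cores = pd.concat(
    [
        simulate_cells(400, 0.8, (0.25, 0.25, 0.25, 0.25), seed=0, core_id="c1"),
        simulate_cells(350, 0.8, (0.10, 0.30, 0.40, 0.20), seed=1, core_id="c2"),
        simulate_cells(60, 0.8, (1.0, 0.0, 0.0, 0.0), seed=2, core_id="c3"),
    ]
)

per_core = score_cells(cores, panel)
print(per_core[per_core["biomarker"] == "PTEN"][
    ["core_id", "n_tumour_cells", "percent_positive", "h_score", "qc_pass"]
])
# c3 has < 100 tumour cells: qc_pass False, its scores are NaN and it is
# ignored by the patient-level aggregate below.

per_patient = patient_scores(per_core, panel)
print("\nper-patient scores (mean of qc-passing cores):")
print(per_patient.round(1))
# A PTEN H-score near 150 for c1 reflects its uniform intensity mix
# (0.25 * (0 + 100 + 200 + 300) = 150); c2's mix is shifted high, so its
# H-score is larger, and the patient value is the mean of the two.
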