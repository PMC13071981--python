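# Data dictionary

All interchange tables are CSV with a header row; patient ids are 1-based
integers; times are months; `event` is 1 = relapse, 0 = censored.

## Cell table (input to scoring; output of `simulate_cells`)

| column | type | meaning |
|---|---|---|
| patient_id | int | patient the core belongs to |
| core_id | str | tissue-microarray core identifier |
| cell_class | str | `tumour` or `stroma` (classifier output; stroma never scored) |
| od_nuclear | float ≥ 0 | mean DAB optical density over the nucleus |
| od_cytoplasm | float ≥ 0 | … over the cytoplasm |
| od_perinuclear | float ≥ 0 | … over the perinuclear ring |
| od_cell | float ≥ 0 | … over the whole cell |

`read_cell_table(path, column_map=...)` renames export-dialect columns to
these canonical names.

## Per-core score table (output of `score_cells`)

patient_id, core_id, biomarker, n_tumour_cells, percent_positive,
h_score (NaN for percent-positive readouts), qc_pass (n_tumour_cells ≥ 100).

## Patient cohort table (output of `simulate_cohort`; input to the pipeline)

| column | type | meaning |
|---|---|---|
| patient_id | int | |
| subtype_true | str | generative subtype (synthetic cohorts only) |
| er_percent, pr_percent | float 0–100 | % positively stained nuclei |
| er_intensity, pr_intensity | int 0–3 | dominant staining intensity |
| her2_positive | bool | HER2 status (adjudicated upstream) |
| ki67_percent | float 0–100 | % Ki67-positive nuclei |
| TOP2A | float 0–100 | % positive tumour nuclei |
| PTEN, EGFR, IGF1R, pmTOR_wholecell | float 0–300 | H-scores |
| pmTOR_perinuclear | float 0–100 | % positive perinuclear staining |
| high_`<biomarker>` | bool | generative high flag (synthetic only) |
| time_months | float | relapse-free survival time |
| event | int 0/1 | 1 = relapse observed |

`assign_subtypes` adds: er_status, pr_status, ki67_status (booleans or
empty when missing) and subtype (`LuminalA`, `LuminalB_HER2neg`,
`LuminalB_HER2pos`, `HER2_enriched`, `TNBC`, `Unknown`).

## Threshold table (`thresholds.csv`)

biomarker, subtype_group (`|`-joined), method (median/scan/fixed), cutoff,
logrank_p, hr, n_high, n_low, note.

## Signature table (`signature.csv`)

patient_id, subtype, comp_`<biomarker>` (−1/0/+1), score (−6..+6),
stratum3 (`>0`/`=0`/`<0`), stratum2 (`>0`/`<=0`), included (False for
Luminal A / Unknown; strata empty then).

## KM curves (`km_curves.csv`)

time, survival, at_risk, stratum — tidy step functions per binary stratum,
ready for plotting.

## Report (`report.json`)

provenance (package, version, seed, config_hash, mode, policies), cohort
summary, per-biomarker thresholds, signature evaluation (three-group and
binary log-rank blocks, multivariate Cox, ROC per horizon, 5-year Fisher
table), and report_hash (SHA-256 of the canonical JSON).
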