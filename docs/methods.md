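# Methods

This note documents the models and conventions behind `ihcsig`: what each
stage computes, which choices were genuinely open and how they were made,
and what the synthetic cohorts do and do not establish about real data.

## Cell-level scoring

Input is a tidy cell table as exported by digital-pathology software after
tumour/stroma classification: one row per detected cell with a DAB optical
density per subcellular compartment (nucleus, cytoplasm, perinuclear ring,
whole cell). Scoring never touches stromal cells.

*Intensity binning.* Optical density maps to ordinal intensity 0..K by
right-open thresholds: intensity = number of thresholds ≤ density. The
shipped thresholds (0.2, 0.4, 0.6, plus 0.8 for 0–4 scales) are an imaging
convention, not a published constant, and are overridable per biomarker.
Likewise, which markers use the 0–4 scale is not published; all default to
0–3 and any can be switched in its `BiomarkerSpec`.

*Quality control.* A core is scoreable only with ≥ 100 tumour cells; the
boundary is inclusive (100 passes, 99 fails).

*Patient aggregation.* The tissue microarray represents each patient in
triplicate, but the aggregation rule is not published. The default is the
mean of qc-passing cores (median available via `agg="median"`); a patient
with no passing core is missing for that biomarker.

*p-mTOR.* One stain yields two readouts: whole-cell H-score and perinuclear
percent positive, implemented as two `BiomarkerSpec`s over different
density columns of the same cells.

## Subtyping

The St Gallen surrogate rules with Allred-based ER/PR calls (proportion
score ≥ 2 and total ≥ 3 — equivalent to ≥ 1% positive nuclei at any
nonzero intensity on the realisable domain, which the suite asserts
exhaustively) and a strictly-greater-than-14% Ki67 rule. Allred proportion
bin edges follow the standard convention (0%; <1%; 1–10%; >10–1/3; >1/3–2/3;
>2/3). HER2 is a boolean input; ISH/IHC-score adjudication is upstream of
this package. A marker that the decision path needs but lacks yields
Unknown, kept in the cohort but excluded from subtype-specific analyses.

## Threshold selection

Each biomarker is dichotomised within its subtype group (the group where it
showed a survival association; the shipped groups are TOP2A in ER−
disease, PTEN in HER2+ plus Luminal B HER2−, EGFR everywhere except
Luminal A, IGF1R in Luminal B HER2−, whole-cell p-mTOR in Luminal B,
perinuclear p-mTOR in HER2+). The source material is internally
inconsistent about the PTEN and IGF1R groups between its narrative and its
tables; the tables (which agree with the applicability matrix) are
followed.

The selection policy mirrors the published framework: the within-group
median split is preferred when it is itself significant, being the
unbiased choice; otherwise the cutoff scan's optimum is adopted if it is
significant and differs notably from the median (relative cutoff
difference above a configurable margin, default 20%). Scan candidates are
midpoints between consecutive distinct scores; splits leaving either arm
below `min_group_frac` (default 0.1, the common convention in
cutoff-scanning tools) are inadmissible. The scanned minimal p is reported
uncorrected by default, matching the referenced online tool; the test
suite demonstrates the resulting optimism under the null, and
`correct=True` applies a Bonferroni factor over the candidate count.

EGFR's published rule is qualitative ("extremely strong staining"); it is
operationalised as the 95th percentile of the non-Luminal-A cohort,
config-overridable, and flagged as a convention.

Ties at a cutoff score "high" (value ≥ cutoff); Ki67's strict rule is the
deliberate exception in the subtyping module.

## Signature

The six ±1 calls are summed; 0 is contributed by a missing measurement.
The zero-for-missing rule is inferred rather than stated: it is the only
reading under which six ±1 terms produce odd composite scores, and odd
scores dominate the published distribution. The alternative — excluding
patients with any missing component — is available (`missing_policy=
"exclude"`). Two applicability modes are first-class: `cohort_wide`
(default) scores every biomarker in every included patient with its
published threshold, which reuses thresholds in subtypes where the
biomarker showed no association and is the main driver of the negative
skew seen in synthetic cohorts; `restricted` zeroes components outside each
biomarker's applicable subtype set. Luminal A and Unknown patients are
excluded from strata in both modes.

## Survival and discrimination statistics

*Log-rank.* Implemented directly (Mantel–Cox chi-squared with the
hypergeometric variance) because the paired hazard-ratio estimator is the
observed/expected form (O₁/E₁)/(O₂/E₂) with CI
exp(log HR ± 1.96·√(1/E₁ + 1/E₂)) — the "log-rank HR" convention of
clinical graphing software — which survival libraries do not expose.
lifelines' log-rank is the independent cross-check in the tests (agreement
to 1e-6), and an exact permutation oracle validates the p-value on small
fixtures. A stratum with zero events gives a degenerate HR (0 or ∞),
reported with a one-sided CI and a flag. Orientation: the test group is
high expression / high score, so HR < 1 is protective.

*Cox.* lifelines `CoxPHFitter` (Efron ties, Wald CIs), behind a surface
that additionally rejects rank-deficient designs before fitting.

*ROC.* The positive class is "remained relapse-free" and higher scores
predict it, so sensitivity at the score > 0 cutoff is the fraction of
relapse-free patients called high and specificity the fraction of relapsed
patients called low, matching the published orientation. Outcomes are
binarised at a horizon (any follow-up time, and 60 months — both are
computed because the source is ambiguous between them); patients censored
before the horizon carry no label and are excluded by default
(`censored_as_negative` available). The AUC is the Mann–Whitney rank
statistic; its CI uses the Hanley–McNeil standard error. The cited
Wilson/Brown method is a proportion CI, not directly an AUC interval; the
substitution is deliberate and labelled here.

*Group comparisons.* Kruskal–Wallis (scipy) with Dunn's post hoc pairwise
z-tests on joint ranks, Bonferroni-adjusted; Dunn's procedure is
implemented in-package because no installed library provides it.
Correlations are Spearman by default with the qualitative banding
|r| < 0.4 weak, 0.4–0.7 moderate, > 0.7 strong.

## Synthetic cohorts

The generator emulates the modelled study's conditions: subtype prevalences
79/64/33/39/72 over 287 known-subtype patients (plus ~2% unknown via a
missing ER readout); six readouts from truncated normals on their native
scales whose locations follow the published subtype ordering (TOP2A and
EGFR highest in TNBC, PTEN and whole-cell p-mTOR lowest in TNBC,
perinuclear p-mTOR flat), with group medians pinned to the published
median-derived cutoffs (PTEN 100, IGF1R 219); completely-at-random
missingness at the published per-biomarker rates (20, 28, 22, 25, 12, 12
of 293); and relapse times from an exponential proportional-hazards model —
the simplest model satisfying the proportional-hazards assumption of the
downstream Cox analyses — where biomarker-high status multiplies the
subtype baseline hazard by the published hazard ratios (0.287, 0.356,
0.2979, 0.2816, 0.3832, 0.2977) within the biomarker's applicable
subtypes. An optional signature-level hazard ratio multiplies the hazard
for patients whose generative composite score is positive, used by the
parameter-recovery experiments. Baseline hazards are back-computed from the
published per-subtype relapse fractions over a 120-month administrative
censoring window; that window is a convention (follow-up duration is not
published), and because the published fractions already include biomarker
effects, simulated marginal event rates sit somewhat below them.

Determinism: one seeded generator, fixed draw order (subtype, receptor/Ki67
markers, biomarker scores, missingness, relapse times); identical config +
seed reproduces tables byte for byte.

What the generator does **not** model: spatial structure or images, core-
level heterogeneity of patient triplicates (patient scores are drawn
directly), joint dependence between biomarkers beyond their shared subtype,
informative censoring, and any joint-distribution feature of the real
cohort beyond the stated marginals. Passing tests therefore establish that
the statistical machinery is correct under its stated model, not that the
published effect sizes would replicate in new data.

A consequence worth noting: biomarker-high status correlates with subtype,
and subtypes differ in baseline hazard, so *marginal* high-vs-low contrasts
in simulated data are confounded by subtype exactly as they would be in a
real cohort. Calibration experiments therefore target the subtype-adjusted
Cox estimand, which equals the configured hazard ratio under the model.

## Problem sizes and numerical conventions

Test and calibration problem sizes are chosen for tight Monte-Carlo error
at interactive runtimes: prevalence checks at n = 100 000, hazard-ratio
recovery at n = 2000 over 50 seeds (95% CI coverage required ≥ 90%),
permutation oracles at n ≤ 12, brute-force cutoff-scan equivalence at
n ≤ 30. Scores are rounded to 3 decimals in generated tables; report JSON
rounds floats to 10 significant digits before hashing; NaN/±∞ serialise as
null/"inf". Degenerate inputs (constant score vectors, empty strata,
zero-event groups, rank-deficient designs) are flagged or rejected with
named errors rather than silently propagated.

## Known limitations

- The OD→intensity thresholds, triplicate aggregation rule, EGFR cutoff and
  censoring window are conventions standing in for unpublished details;
  each is overridable in config.
- Cohort-wide threshold reuse outside a biomarker's associated subtypes is
  one of two defensible readings; both modes are implemented and reported.
- The headline cohort statistics of the modelled study (binary HR 0.2251,
  AUC 0.7302) depend on its unreleased data and are not reproduction
  targets; synthetic runs report the same statistics under the generator's
  conditions instead.
- No time-dependent covariates, competing risks, or weighted signature
  variants.
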