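"""End-to-end run orchestration.

A run goes: cohort acquisition (synthetic, a cell table plus clinical
table, or a ready patient table) -> subtype assignment -> per-biomarker
high/low thresholds (estimated within subtype groups, or the published
fixed cutoffs) -> composite signature -> survival and ROC evaluation.
Every stage writes a CSV under the output directory and every statistic
lands in a JSON report carrying a provenance block (seed, config hash,
package version) and a deterministic report hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import (
    APPLICABLE_SUBTYPES,
    BIOMARKERS,
    EGFR_EXTREME_QUANTILE,
    PUBLISHED_THRESHOLDS,
)
from .cutpoints import ThresholdResult, evaluate_cutoff, median_cutoff, scan_cutoffs, select_threshold
from .scoring import patient_scores, read_cell_table, score_cells
from .signature import score_cohort, score_histogram
from .simulate import SimulationConfig, simulate_cohort
from .subtypes import assign_subtypes
from .survival import cox_fit, fisher_2x2, km_estimate, logrank_test, roc_at_horizon

log = logging.getLogger("ihcsig")

MODES = ("synthetic", "cell-tables", "patient-table")

#: Columns a patient-level table must provide.
PATIENT_COLUMNS = (
    "patient_id",
    "er_percent",
    "er_intensity",
    "pr_percent",
    "pr_intensity",
    "her2_positive",
    "ki67_percent",
    "time_months",
    "event",
)


@dataclass
class RunConfig:
    """One reproducible analysis run.

    ``threshold_policy``: ``fixed`` applies the published cutoffs (EGFR's
    qualitative rule becomes the 95th percentile of the non-Luminal-A
    cohort); ``estimate`` derives thresholds from the data by median split
    and cutoff scan within each biomarker's subtype group.
    ``applicability_mode`` selects cohort-wide component scoring (default)
    or scoring restricted to each biomarker's applicable subtypes.
    ``horizons`` are the ROC evaluation horizons in months (``null``/None =
    any follow-up time).
    """

    mode: str = "synthetic"
    seed: int = 0
    n_patients: int = 293
    cell_table: str | None = None
    patient_table: str | None = None
    threshold_policy: str = "fixed"
    fixed_thresholds: dict = field(default_factory=dict)
    applicability_mode: str = "cohort_wide"
    missing_policy: str = "zero"
    min_group_frac: float = 0.1
    alpha: float = 0.05
    horizons: tuple = (None, 60.0)
    cox_covariates: tuple = ()
    output_dir: str = "ihcsig_run"
    resume: bool = False
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.threshold_policy not in ("fixed", "estimate"):
            raise ValueError("threshold_policy must be 'fixed' or 'estimate'")
        if self.mode == "cell-tables" and not self.cell_table:
            raise ValueError("cell-tables mode requires cell_table")
        if self.mode in ("cell-tables", "patient-table") and not self.patient_table:
            raise ValueError(f"{self.mode} mode requires patient_table")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "horizons" in raw and raw["horizons"] is not None:
            raw["horizons"] = tuple(raw["horizons"])
        if "cox_covariates" in raw:
            raw["cox_covariates"] = tuple(raw["cox_covariates"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant config (output location and resume
        flag do not affect results and are excluded)."""
        d = asdict(self)
        d.pop("output_dir", None)
        d.pop("resume", None)
        return hashlib.sha256(_canonical_json(d).encode()).hexdigest()[:16]


def _canonical_json(obj) -> str:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    return json.dumps(obj, sort_keys=True, default=default)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        if np.isnan(v):
            return None
        if np.isinf(v):
            return "inf" if v > 0 else "-inf"
        return float(f"{v:.{ndigits}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# Stages


def build_cohort(config: RunConfig) -> pd.DataFrame:
    """Acquire the patient-level table for the configured input mode."""
    if config.mode == "synthetic":
        sim = SimulationConfig(n_patients=config.n_patients, seed=config.seed, **config.simulation)
        return simulate_cohort(sim)
    patients = pd.read_csv(config.patient_table)
    missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise ValueError(f"patient table missing column(s): {', '.join(missing)}")
    if config.mode == "cell-tables":
        cells = read_cell_table(config.cell_table)
        scores = patient_scores(score_cells(cells))
        patients = patients.drop(columns=[m for m in BIOMARKERS if m in patients.columns])
        patients = patients.merge(scores, on="patient_id", how="left")
    missing_markers = [m for m in BIOMARKERS if m not in patients.columns]
    if missing_markers:
        raise ValueError(f"patient table missing biomarker column(s): {', '.join(missing_markers)}")
    return patients


def estimate_thresholds(cohort: pd.DataFrame, config: RunConfig) -> dict[str, ThresholdResult]:
    """Per-biomarker thresholds within each biomarker's subtype group.

    Fixed policy: published cutoffs, evaluated (log-rank HR/p) on this
    cohort for the report but never re-estimated. Estimate policy: median
    split vs cutoff scan, adjudicated by :func:`select_threshold`.
    """
    out: dict[str, ThresholdResult] = {}
    for m in BIOMARKERS:
        group = tuple(sorted(APPLICABLE_SUBTYPES[m]))
        sub = cohort[cohort["subtype"].isin(group)]
        scores = sub[m].to_numpy(float)
        times = sub["time_months"].to_numpy(float)
        events = sub["event"].to_numpy(int)
        if config.threshold_policy == "fixed":
            if m in config.fixed_thresholds:
                cutoff = float(config.fixed_thresholds[m])
            elif m in PUBLISHED_THRESHOLDS:
                cutoff = PUBLISHED_THRESHOLDS[m]
            else:  # EGFR: extreme-staining rule as a cohort percentile
                non_luma = cohort.loc[cohort["subtype"] != "LuminalA", m].dropna()
                cutoff = float(np.nanquantile(non_luma, EGFR_EXTREME_QUANTILE))
            res = evaluate_cutoff(scores, times, events, cutoff, m, group, method="fixed")
            res.note = "fixed threshold (no estimation performed)"
            out[m] = res
        else:
            med = evaluate_cutoff(scores, times, events, median_cutoff(scores), m, group, method="median")
            _, best = scan_cutoffs(
                scores, times, events, min_group_frac=config.min_group_frac,
                biomarker=m, subtype_group=group,
            )
            out[m] = select_threshold(med, best, alpha=config.alpha)
        log.info("threshold %-18s %-8s cutoff=%-8.4g p=%.3g", m, out[m].method, out[m].cutoff, out[m].logrank_p)
    return out


def _logrank_block(d1: pd.DataFrame, d2: pd.DataFrame) -> dict:
    lr = logrank_test(
        d1["time_months"], d1["event"], d2["time_months"], d2["event"]
    )
    return {
        "chi2": lr.chi2, "p": lr.p, "hr": lr.hr, "hr_ci": list(lr.hr_ci),
        "n": list(lr.n), "degenerate": lr.degenerate,
    }


def evaluate_signature(cohort: pd.DataFrame, signature: pd.DataFrame, config: RunConfig) -> dict:
    """Survival + ROC evaluation of the composite signature strata."""
    merged = cohort.merge(signature[["patient_id", "score", "stratum3", "stratum2", "included"]], on="patient_id")
    inc = merged[merged["included"]]
    report: dict = {
        "n_total": int(len(merged)),
        "n_included": int(len(inc)),
        "n_excluded_luminalA_or_unknown": int((~merged["included"]).sum()),
        "score_histogram": score_histogram(signature).to_dict(orient="list"),
    }

    strata3 = {s: inc[inc["stratum3"] == s] for s in (">0", "=0", "<0")}
    report["three_group"] = {
        "n": {s: int(len(d)) for s, d in strata3.items()},
        "pos_vs_zero": _logrank_block(strata3[">0"], strata3["=0"]) if len(strata3["=0"]) and len(strata3[">0"]) else None,
        "pos_vs_neg": _logrank_block(strata3[">0"], strata3["<0"]) if len(strata3["<0"]) and len(strata3[">0"]) else None,
    }
    pos = inc[inc["stratum2"] == ">0"]
    nonpos = inc[inc["stratum2"] == "<=0"]
    report["binary"] = _logrank_block(pos, nonpos) if len(pos) and len(nonpos) else None

    # multivariate Cox: binary signature plus configured covariates
    # (subtype indicators by default)
    X = pd.DataFrame({"signature_pos": (inc["stratum2"] == ">0").astype(float)})
    if config.cox_covariates:
        for c in config.cox_covariates:
            X[c] = inc[c].astype(float).to_numpy()
    else:
        dummies = pd.get_dummies(inc["subtype"], prefix="subtype", drop_first=True)
        for c in dummies.columns:
            if dummies[c].nunique() > 1:
                X[c] = dummies[c].astype(float).to_numpy()
    try:
        cox = cox_fit(inc["time_months"], inc["event"], X)
        report["cox_multivariate"] = {
            cov: {"hr": row["hr"], "hr_ci": [row["hr_lo"], row["hr_hi"]], "p": row["p"]}
            for cov, row in cox.iterrows()
        }
    except (ValueError, np.linalg.LinAlgError) as exc:
        report["cox_multivariate"] = {"error": str(exc)}

    report["roc"] = {}
    for hz in config.horizons:
        try:
            roc = roc_at_horizon(inc["score"], inc["time_months"], inc["event"], horizon=hz)
            key = "any_time" if hz is None else f"{hz:g}_months"
            report["roc"][key] = {
                "auc": roc.auc, "auc_ci": list(roc.auc_ci), "p": roc.p,
                "sensitivity": roc.sensitivity, "specificity": roc.specificity,
                "n_relapse_free": roc.n_relapse_free, "n_relapsed": roc.n_relapsed,
                "n_excluded": roc.n_excluded,
            }
        except ValueError as exc:
            report["roc"]["any_time" if hz is None else f"{hz:g}_months"] = {"error": str(exc)}

    # relapse-by-5-years contingency of the binary strata
    hz = 60.0
    determined = inc[(inc["event"] == 1) & (inc["time_months"] <= hz) | (inc["time_months"] > hz)]
    if len(determined):
        relapse = (determined["event"] == 1) & (determined["time_months"] <= hz)
        high = determined["stratum2"] == ">0"
        table = [
            [int((high & ~relapse).sum()), int((high & relapse).sum())],
            [int((~high & ~relapse).sum()), int((~high & relapse).sum())],
        ]
        report["fisher_5yr"] = {"table": table, "p": fisher_2x2(table)}
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full run; returns the report dict (also written to disk).

    Stage outputs (cohort, thresholds, signature, KM curves) are CSVs under
    ``config.output_dir``; with ``resume=True`` a stage whose CSV already
    exists is loaded instead of recomputed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort_path = outdir / "cohort.csv"
    if config.resume and cohort_path.exists():
        log.info("resuming: loading %s", cohort_path)
        cohort = pd.read_csv(cohort_path)
    else:
        cohort = build_cohort(config)
        cohort = assign_subtypes(cohort)
        cohort.to_csv(cohort_path, index=False)

    if "subtype" not in cohort.columns:
        cohort = assign_subtypes(cohort)

    thresholds = estimate_thresholds(cohort, config)
    thr_table = pd.DataFrame(
        [
            {
                "biomarker": t.biomarker, "subtype_group": "|".join(t.subtype_group),
                "method": t.method, "cutoff": t.cutoff, "logrank_p": t.logrank_p,
                "hr": t.hr, "n_high": t.n_high, "n_low": t.n_low, "note": t.note,
            }
            for t in thresholds.values()
        ]
    )
    thr_table.to_csv(outdir / "thresholds.csv", index=False)

    signature = score_cohort(
        cohort, thresholds, mode=config.applicability_mode, missing_policy=config.missing_policy
    )
    signature.to_csv(outdir / "signature.csv", index=False)

    evaluation = evaluate_signature(cohort, signature, config)

    merged = cohort.merge(signature[["patient_id", "stratum2", "included"]], on="patient_id")
    km_rows = []
    for label, grp in merged[merged["included"]].groupby("stratum2"):
        km = km_estimate(grp["time_months"], grp["event"])
        km["stratum"] = label
        km_rows.append(km)
    if km_rows:
        pd.concat(km_rows).to_csv(outdir / "km_curves.csv", index=False)

    report = {
        "provenance": {
            "package": "ihcsig",
            "version": __version__,
            "seed": config.seed,
            "mode": config.mode,
            "config_hash": config.config_hash(),
            "threshold_policy": config.threshold_policy,
            "applicability_mode": config.applicability_mode,
        },
        "cohort": {
            "n_patients": int(len(cohort)),
            "subtype_counts": cohort["subtype"].value_counts().sort_index().to_dict(),
            "n_events": int(cohort["event"].sum()),
        },
        "thresholds": {
            m: {
                "cutoff": t.cutoff, "method": t.method, "logrank_p": t.logrank_p,
                "hr": t.hr, "n_high": t.n_high, "n_low": t.n_low,
                "subtype_group": list(t.subtype_group), "note": t.note,
            }
            for m, t in thresholds.items()
        },
        "signature": evaluation,
    }
    report = _round_floats(report)
    report_json = _canonical_json(report)
    report["report_hash"] = hashlib.sha256(report_json.encode()).hexdigest()
    (outdir / "report.json").write_text(_canonical_json(report))
    log.info("run complete: %s (hash %s)", outdir / "report.json", report["report_hash"][:12])
    return report
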