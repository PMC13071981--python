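"""Per-cell to per-patient IHC scoring.

Input is a tidy cell table (one row per detected cell) as exported from a
digital-pathology platform after tumour/stroma classification: columns
``patient_id``, ``core_id``, ``cell_class`` (``tumour``/``stroma``) and one
DAB optical density per subcellular compartment. Stromal cells never
contribute to a score. A core passes quality control only if it contains at
least :data:`MIN_TUMOUR_CELLS` tumour cells; a patient's score for a
biomarker aggregates the qc-passing cores (triplicate cores per patient in
the TMA design).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .biomarkers import BIOMARKERS, BiomarkerSpec, default_panel

#: Minimum tumour cells for a core to be scoreable.
MIN_TUMOUR_CELLS = 100

TUMOUR = "tumour"
STROMA = "stroma"

CELL_COLUMNS = (
    "patient_id",
    "core_id",
    "cell_class",
    "od_nuclear",
    "od_cytoplasm",
    "od_perinuclear",
    "od_cell",
)


def bin_intensity(density, spec: BiomarkerSpec):
    """Map optical density to ordinal staining intensity.

    Intensity is the number of thresholds in ``spec.od_bins`` that the
    density meets or exceeds (right-open bins), so intensity 0 covers
    ``[0, od_bins[0])`` and the top bin is unbounded. Accepts scalars or
    arrays.

    Raises
    ------
    ValueError
        If any density is negative.
    """
    dens = np.asarray(density, dtype=float)
    if np.any(dens < 0):
        raise ValueError("optical density must be >= 0")
    out = np.searchsorted(np.asarray(spec.od_bins), dens, side="right")
    return int(out) if np.isscalar(density) else out


def qc_core(cells: pd.DataFrame) -> bool:
    """Quality-control flag for one core: >= 100 tumour cells required.

    Raises
    ------
    ValueError
        If rows carry mixed core ids.
    """
    if len(cells) and cells["core_id"].nunique() > 1:
        raise ValueError("qc_core expects cells from a single core")
    return int((cells["cell_class"] == TUMOUR).sum()) >= MIN_TUMOUR_CELLS


def _tumour_intensities(cells: pd.DataFrame, spec: BiomarkerSpec) -> np.ndarray:
    tum = cells.loc[cells["cell_class"] == TUMOUR, spec.od_column]
    if tum.empty:
        raise ValueError("no tumour cells to score")
    return bin_intensity(tum.to_numpy(), spec)


def percent_positive(cells: pd.DataFrame, spec: BiomarkerSpec) -> float:
    """Percentage of tumour cells with nonzero intensity at the spec's compartment."""
    intens = _tumour_intensities(cells, spec)
    return 100.0 * float(np.mean(intens >= 1))


def h_score(cells: pd.DataFrame, spec: BiomarkerSpec) -> float:
    """Intensity-weighted histochemical score.

    H-score = sum_k k * (% tumour cells at intensity k) for
    k = 1..max_intensity, ranging 0 to 100 * max_intensity.
    """
    intens = _tumour_intensities(cells, spec)
    pct = 100.0 * np.bincount(intens, minlength=spec.max_intensity + 1) / len(intens)
    return float(np.dot(np.arange(1, spec.max_intensity + 1), pct[1:]))


def score_core(cells: pd.DataFrame, spec: BiomarkerSpec) -> dict:
    """Score one core for one biomarker, returning a CoreScore record.

    The score field used depends on the spec's method; ``h_score`` is NaN
    for percent-positive readouts. Failing cores still report cell counts
    but carry NaN scores.
    """
    if len(cells) and cells["core_id"].nunique() > 1:
        raise ValueError("score_core expects cells from a single core")
    n_tumour = int((cells["cell_class"] == TUMOUR).sum()) if len(cells) else 0
    passed = n_tumour >= MIN_TUMOUR_CELLS
    rec = {
        "patient_id": cells["patient_id"].iloc[0] if len(cells) else None,
        "core_id": cells["core_id"].iloc[0] if len(cells) else None,
        "biomarker": spec.name,
        "n_tumour_cells": n_tumour,
        "percent_positive": np.nan,
        "h_score": np.nan,
        "qc_pass": passed,
    }
    if passed:
        rec["percent_positive"] = percent_positive(cells, spec)
        if spec.method == "h_score":
            rec["h_score"] = h_score(cells, spec)
    return rec


def score_cells(
    cell_table: pd.DataFrame,
    panel: Mapping[str, BiomarkerSpec] | None = None,
) -> pd.DataFrame:
    """Score every core in a cell table against every panel biomarker.

    Returns a per-core table with one row per (core, biomarker) and the
    CoreScore columns.
    """
    panel = default_panel() if panel is None else panel
    rows = []
    for _, core_cells in cell_table.groupby(["patient_id", "core_id"], sort=True):
        for spec in panel.values():
            rows.append(score_core(core_cells, spec))
    return pd.DataFrame(rows)


def aggregate_patient(core_scores: pd.DataFrame, agg: str = "mean") -> float:
    """Collapse one patient's core scores for one biomarker to a single value.

    Only qc-passing cores contribute; the aggregate is their mean (or
    median via ``agg``). Returns NaN when no core passes — the patient is
    then missing for this biomarker.

    Raises
    ------
    ValueError
        If rows span multiple patients or biomarkers.
    """
    if core_scores["patient_id"].nunique() > 1:
        raise ValueError("aggregate_patient expects a single patient")
    if core_scores["biomarker"].nunique() > 1:
        raise ValueError("aggregate_patient expects a single biomarker")
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    passing = core_scores[core_scores["qc_pass"]]
    if passing.empty:
        return float("nan")
    col = "h_score" if passing["h_score"].notna().any() else "percent_positive"
    return float(getattr(passing[col], agg)())


def patient_scores(
    core_scores: pd.DataFrame,
    panel: Mapping[str, BiomarkerSpec] | None = None,
    agg: str = "mean",
) -> pd.DataFrame:
    """Aggregate a per-core score table to a patient x biomarker table."""
    panel = default_panel() if panel is None else panel
    out: dict[str, dict] = {}
    for (pid, marker), grp in core_scores.groupby(["patient_id", "biomarker"], sort=True):
        out.setdefault(pid, {})[marker] = aggregate_patient(grp, agg=agg)
    table = pd.DataFrame.from_dict(out, orient="index").rename_axis("patient_id")
    cols = [m for m in panel if m in table.columns]
    return table[cols].reset_index()


def read_cell_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited cell table, renaming export-dialect columns.

    ``column_map`` maps the file's column names to the canonical
    :data:`CELL_COLUMNS`. Missing canonical columns raise a schema error
    naming the column.
    """
    table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns={src: dst for src, dst in column_map.items()})
    missing = [c for c in CELL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table missing column(s): {', '.join(missing)}")
    return table
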