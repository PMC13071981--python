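"""The composite six-component biomarker signature.

Each of the six readouts contributes +1 when the patient is high for that
biomarker, -1 when low, and 0 when the measurement is missing (or, under
the restricted-applicability mode, when the patient's subtype lies outside
the biomarker's applicable set). The signature score is the plain sum:

    score = TOP2A + PTEN + EGFR + IGF1R + pmTOR_wholecell + pmTOR_perinuclear

giving a possible range of -6..+6. Patients are stratified three ways
(score > 0, = 0, < 0) and two ways (> 0 vs <= 0). Luminal A and
unknown-subtype patients are excluded: no component showed a survival
association in Luminal A.

The zero-for-missing rule is an interpretive choice: it is the only reading
under which six +/-1 terms can produce the odd scores observed in practice.
The alternative (drop patients with any missing component) is available via
``missing_policy="exclude"``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .biomarkers import APPLICABLE_SUBTYPES, BIOMARKERS, UNKNOWN_SUBTYPE
from .cutpoints import ThresholdResult

EXCLUDED_SUBTYPES = frozenset({"LuminalA", UNKNOWN_SUBTYPE})


def component_score(
    value: float,
    threshold: ThresholdResult | float,
    subtype: str | None = None,
    applicable: frozenset[str] | None = None,
    restricted: bool = False,
) -> int:
    """Single-biomarker contribution: +1 high, -1 low, 0 missing.

    ``threshold`` may be a ThresholdResult or a bare cutoff value; high
    means value >= cutoff. With ``restricted=True`` a patient whose subtype
    is outside ``applicable`` contributes 0 regardless of the measurement.
    """
    cutoff = threshold.cutoff if isinstance(threshold, ThresholdResult) else float(threshold)
    if restricted and applicable is not None and subtype not in applicable:
        return 0
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return 0
    return 1 if value >= cutoff else -1


def signature_score(components) -> int:
    """Sum of the six component scores (each in {-1, 0, +1})."""
    comp = list(components)
    if len(comp) != len(BIOMARKERS):
        raise ValueError(f"expected {len(BIOMARKERS)} components, got {len(comp)}")
    if any(c not in (-1, 0, 1) for c in comp):
        raise ValueError("components must be -1, 0 or +1")
    return int(sum(comp))


def stratify(score: int) -> tuple[str, str]:
    """Three-group and binary strata for a signature score."""
    s3 = ">0" if score > 0 else ("=0" if score == 0 else "<0")
    s2 = ">0" if score > 0 else "<=0"
    return s3, s2


def score_cohort(
    cohort: pd.DataFrame,
    thresholds: Mapping[str, ThresholdResult | float],
    mode: str = "cohort_wide",
    missing_policy: str = "zero",
) -> pd.DataFrame:
    """Per-patient signature table for a subtyped cohort.

    Parameters
    ----------
    cohort : DataFrame
        Must carry ``patient_id``, ``subtype`` and one column per readout.
    thresholds : mapping
        Cutoff (value or ThresholdResult) for each of the six readouts.
    mode : str
        ``cohort_wide`` scores every biomarker in every patient with its
        published threshold; ``restricted`` zeroes components for subtypes
        outside the biomarker's applicable set. Both are legitimate
        readings of the published construction and can be reported side by
        side.
    missing_policy : str
        ``zero`` (default) or ``exclude`` (patients with any missing
        component among the applicable ones are dropped from strata).

    Returns a table with component columns (``comp_<biomarker>``), the
    ``score``, ``stratum3``/``stratum2`` labels and the ``included`` flag
    (False for Luminal A / Unknown, whose strata are empty strings).
    """
    if mode not in ("cohort_wide", "restricted"):
        raise ValueError("mode must be 'cohort_wide' or 'restricted'")
    if missing_policy not in ("zero", "exclude"):
        raise ValueError("missing_policy must be 'zero' or 'exclude'")
    missing = [m for m in BIOMARKERS if m not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {', '.join(missing)}")
    missing_thr = [m for m in BIOMARKERS if m not in thresholds]
    if missing_thr:
        raise ValueError(f"no threshold for: {', '.join(missing_thr)}")

    rows = []
    for row in cohort.itertuples(index=False):
        subtype = getattr(row, "subtype")
        comps = {
            m: component_score(
                getattr(row, m),
                thresholds[m],
                subtype=subtype,
                applicable=APPLICABLE_SUBTYPES.get(m),
                restricted=(mode == "restricted"),
            )
            for m in BIOMARKERS
        }
        score = signature_score(comps.values())
        included = subtype not in EXCLUDED_SUBTYPES
        if included and missing_policy == "exclude":
            measured = all(not pd.isna(getattr(row, m)) for m in BIOMARKERS)
            included = measured
        s3, s2 = stratify(score) if included else ("", "")
        rec = {"patient_id": getattr(row, "patient_id"), "subtype": subtype}
        rec.update({f"comp_{m}": c for m, c in comps.items()})
        rec.update({"score": score, "stratum3": s3, "stratum2": s2, "included": included})
        rows.append(rec)
    return pd.DataFrame(rows)


def score_histogram(signature_table: pd.DataFrame) -> pd.DataFrame:
    """Frequency of each observed signature score among included patients."""
    inc = signature_table[signature_table["included"]]
    counts = inc["score"].value_counts().sort_index()
    return pd.DataFrame(
        {"score": counts.index, "n": counts.to_numpy(), "percent": 100 * counts.to_numpy() / max(len(inc), 1)}
    )
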