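"""St Gallen surrogate molecular subtyping from ER/PR/HER2/Ki67 readouts.

Hormone-receptor positivity follows the Allred convention: proportion
score >= 2 together with total score (proportion + intensity) >= 3, which
is equivalent to at least 1% of nuclei staining at any nonzero intensity.
Ki67 is called positive strictly above 14% positive nuclei. HER2 status is
taken as a boolean input (the ISH/IHC-score workflow happens upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomarkers import SUBTYPES, UNKNOWN_SUBTYPE

KI67_CUTOFF = 14.0  # percent; positive is strictly greater


@dataclass(frozen=True)
class SubtypeMarkers:
    """ER/PR/HER2/Ki67 readouts for one patient.

    ``er_percent``/``pr_percent`` are % positively stained nuclei,
    ``er_intensity``/``pr_intensity`` the dominant staining intensity (0-3),
    ``ki67_percent`` the % Ki67-positive nuclei. Any field may be NaN/None,
    in which case the subtype is Unknown.
    """

    er_percent: float
    er_intensity: int
    pr_percent: float
    pr_intensity: int
    her2_positive: bool | None
    ki67_percent: float


def allred_proportion(percent: float) -> int:
    """Allred proportion score from % positive nuclei.

    Bins: 0 -> 0; (0,1) -> 1; [1,10] -> 2; (10, 1/3] -> 3; (1/3, 2/3] -> 4;
    (2/3, 1] -> 5 (fractions of 100%).
    """
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    if percent == 0:
        return 0
    if percent < 1:
        return 1
    if percent <= 10:
        return 2
    if percent <= 100 / 3:
        return 3
    if percent <= 200 / 3:
        return 4
    return 5


def allred_total(percent: float, intensity: int) -> tuple[int, int]:
    """Allred (proportion score, total score) for one receptor.

    Total = proportion (0-5) + intensity (0-3), range 0-8.
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity must be an integer 0-3")
    prop = allred_proportion(percent)
    return prop, prop + intensity


def receptor_positive(percent: float, intensity: int) -> bool:
    """Positivity rule: proportion score >= 2 and total score >= 3."""
    prop, total = allred_total(percent, intensity)
    return prop >= 2 and total >= 3


def ki67_positive(percent: float) -> bool:
    """Ki67 status: positive strictly above 14% (14% exactly is negative)."""
    if not 0 <= percent <= 100:
        raise ValueError("percent must be in [0, 100]")
    return percent > KI67_CUTOFF


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def st_gallen(markers: SubtypeMarkers) -> str:
    """Assign one of the five St Gallen surrogate subtypes (or Unknown).

    Rules: Luminal A = HR+ HER2- Ki67-; Luminal B HER2- = HR+ HER2- Ki67+;
    Luminal B HER2+ = HR+ HER2+ (any Ki67); HER2-enriched = HR- HER2+;
    TNBC = HR- HER2-. HR+ means ER-positive and/or PR-positive. A marker
    that the decision path actually needs but is missing yields Unknown
    (Ki67 is only consulted on the HR+/HER2- branch); downstream
    subtype-specific analyses skip Unknown patients.
    """
    receptor_fields = (
        markers.er_percent,
        markers.er_intensity,
        markers.pr_percent,
        markers.pr_intensity,
        markers.her2_positive,
    )
    if any(_is_missing(f) for f in receptor_fields):
        return UNKNOWN_SUBTYPE
    hr_pos = receptor_positive(markers.er_percent, int(markers.er_intensity)) or receptor_positive(
        markers.pr_percent, int(markers.pr_intensity)
    )
    her2 = bool(markers.her2_positive)
    if hr_pos and her2:
        return "LuminalB_HER2pos"
    if hr_pos:
        if _is_missing(markers.ki67_percent):
            return UNKNOWN_SUBTYPE
        return "LuminalB_HER2neg" if ki67_positive(markers.ki67_percent) else "LuminalA"
    return "HER2_enriched" if her2 else "TNBC"


def assign_subtypes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add er_status/pr_status/ki67_status/subtype columns to a cohort table.

    Expects columns er_percent, er_intensity, pr_percent, pr_intensity,
    her2_positive, ki67_percent; raises a schema error naming any that is
    absent.
    """
    required = (
        "er_percent",
        "er_intensity",
        "pr_percent",
        "pr_intensity",
        "her2_positive",
        "ki67_percent",
    )
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {', '.join(missing)}")
    out = cohort.copy()
    er, pr, ki, sub = [], [], [], []
    for row in out.itertuples(index=False):
        m = SubtypeMarkers(
            er_percent=row.er_percent,
            er_intensity=row.er_intensity,
            pr_percent=row.pr_percent,
            pr_intensity=row.pr_intensity,
            her2_positive=row.her2_positive,
            ki67_percent=row.ki67_percent,
        )
        er_ok = not (_is_missing(m.er_percent) or _is_missing(m.er_intensity))
        pr_ok = not (_is_missing(m.pr_percent) or _is_missing(m.pr_intensity))
        ki_ok = not _is_missing(m.ki67_percent)
        er.append(receptor_positive(m.er_percent, int(m.er_intensity)) if er_ok else None)
        pr.append(receptor_positive(m.pr_percent, int(m.pr_intensity)) if pr_ok else None)
        ki.append(ki67_positive(m.ki67_percent) if ki_ok else None)
        sub.append(st_gallen(m))
    out["er_status"] = er
    out["pr_status"] = pr
    out["ki67_status"] = ki
    out["subtype"] = sub
    return out
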