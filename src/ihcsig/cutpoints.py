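"""High/low dichotomisation of continuous biomarker scores per subtype group.

Two estimation routes are provided, mirroring the published selection
framework: an unbiased within-group median split, and a cutoff scan that
evaluates the log-rank test at every admissible split and keeps the most
significant one (the approach of online cutoff-optimisation tools). The
scan's minimal p-value is
optimistic — it is a minimum over many correlated tests — and is reported
uncorrected by default to match the cited tool, with an optional
Bonferroni-style correction over the number of candidates.

Patients score "high" when their value is >= the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .survival import LogrankResult, logrank_test


@dataclass
class ThresholdResult:
    """A dichotomisation threshold and its survival association."""

    biomarker: str
    subtype_group: tuple[str, ...]
    method: str  # median | scan | fixed
    cutoff: float
    logrank_p: float = float("nan")
    hr: float = float("nan")
    hr_ci: tuple[float, float] = (float("nan"), float("nan"))
    n_high: int = 0
    n_low: int = 0
    degenerate: bool = False
    note: str = ""


def median_cutoff(scores) -> float:
    """Sample median of the non-missing scores (the unbiased split point).

    Raises
    ------
    ValueError
        With fewer than 2 non-missing scores.
    """
    arr = np.asarray(scores, float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("need >= 2 non-missing scores")
    return float(np.median(arr))


def evaluate_cutoff(
    scores,
    times,
    events,
    cutoff: float,
    biomarker: str = "",
    subtype_group: tuple[str, ...] = (),
    method: str = "fixed",
) -> ThresholdResult:
    """Log-rank association of the high (>= cutoff) vs low split.

    A split leaving one side empty is returned flagged degenerate with no
    test performed.
    """
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    keep = ~np.isnan(scores)
    scores, times, events = scores[keep], times[keep], events[keep]
    high = scores >= cutoff
    res = ThresholdResult(
        biomarker=biomarker,
        subtype_group=tuple(subtype_group),
        method=method,
        cutoff=float(cutoff),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
    )
    if res.n_high == 0 or res.n_low == 0:
        res.degenerate = True
        res.note = "all patients on one side of the cutoff"
        return res
    lr = logrank_test(times[high], events[high], times[~high], events[~high])
    res.logrank_p = lr.p
    res.hr = lr.hr
    res.hr_ci = lr.hr_ci
    res.degenerate = lr.degenerate
    return res


def scan_cutoffs(
    scores,
    times,
    events,
    min_group_frac: float = 0.1,
    biomarker: str = "",
    subtype_group: tuple[str, ...] = (),
    correct: bool = False,
) -> tuple[list[ThresholdResult], ThresholdResult]:
    """Evaluate every candidate split and return (candidates, optimum).

    Candidates are midpoints between consecutive distinct score values;
    those leaving either arm below ``min_group_frac`` of the analysed
    patients are skipped. The optimum minimises the log-rank p, ties broken
    toward the cutoff nearest the median. With ``correct=True`` each p is
    multiplied by the number of candidates (capped at 1) before selection —
    a conservative answer to the scan's optimism.

    Raises
    ------
    ValueError
        With fewer than 10 patients or no admissible candidate.
    """
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    keep = ~np.isnan(scores)
    scores, times, events = scores[keep], times[keep], events[keep]
    n = scores.size
    if n < 10:
        raise ValueError("cutoff scanning requires >= 10 patients")
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    min_n = min_group_frac * n
    med = float(np.median(scores))

    candidates: list[ThresholdResult] = []
    for c in mids:
        n_high = int((scores >= c).sum())
        if n_high < min_n or (n - n_high) < min_n:
            continue
        candidates.append(
            evaluate_cutoff(scores, times, events, c, biomarker, subtype_group, method="scan")
        )
    if not candidates:
        raise ValueError("no admissible candidate cutoff")
    if correct:
        m = len(candidates)
        for cand in candidates:
            cand.logrank_p = min(cand.logrank_p * m, 1.0)
            cand.note = f"p Bonferroni-corrected over {m} candidates"
    best = min(candidates, key=lambda r: (r.logrank_p, abs(r.cutoff - med)))
    return candidates, replace(best)


def select_threshold(
    median_result: ThresholdResult,
    scan_result: ThresholdResult,
    alpha: float = 0.05,
    rel_cutoff_margin: float = 0.2,
) -> ThresholdResult:
    """Choose between the median split and the scan optimum.

    Policy: keep the median split when it is itself significant (it is the
    unbiased choice); otherwise adopt the scan optimum when it is
    significant and its cutoff is notably different from the median —
    relative difference above ``rel_cutoff_margin`` of the median split's
    cutoff magnitude (or absolute difference when the median cutoff is 0).
    Failing both, the median split is returned flagged non-informative.
    The decision is recorded in the result's note.
    """
    if median_result.biomarker != scan_result.biomarker:
        raise ValueError("results describe different biomarkers")
    if not np.isnan(median_result.logrank_p) and median_result.logrank_p < alpha:
        out = replace(median_result)
        out.note = f"median split selected (p={median_result.logrank_p:.3g} < {alpha})"
        return out
    scale = abs(median_result.cutoff)
    diff = abs(scan_result.cutoff - median_result.cutoff)
    notably_different = diff > rel_cutoff_margin * scale if scale > 0 else diff > 0
    if scan_result.logrank_p < alpha and notably_different:
        out = replace(scan_result)
        out.note = (
            f"scan cutoff selected (p={scan_result.logrank_p:.3g}, "
            f"differs from median {median_result.cutoff:g} by {diff:g})"
        )
        return out
    out = replace(median_result)
    out.note = "non-informative: neither split reaches significance; median retained"
    return out
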