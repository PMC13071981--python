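"""Outcome statistics: Kaplan-Meier, log-rank with O/E hazard ratio, Cox
regression, fixed-horizon ROC, contingency and rank tests, correlations.

The two-group log-rank (Mantel-Cox) test is implemented directly because the
hazard-ratio estimator paired with it here is the observed/expected form
HR = (O1/E1)/(O2/E2) with a log-scale CI — the quantity clinical papers
report as the "log-rank HR" — which general-purpose survival libraries do
not expose. Kaplan-Meier curves and Cox proportional-hazards fits are
delegated to lifelines.

Orientation convention: group 1 is the test group (high expression / high
signature score), so HR < 1 means the test group is protected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# Kaplan-Meier


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival curve with at-risk counts.

    Returns a tidy step-function table with columns ``time``, ``survival``
    and ``at_risk`` (the risk set just before each time), starting at
    time 0 with survival 1. Right-censored observations (event flag 0)
    leave the curve unchanged but shrink the risk set.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    grid = surv.index.to_numpy(dtype=float)
    at_risk = np.array([(times >= t).sum() for t in grid])
    return pd.DataFrame({"time": grid, "survival": surv.to_numpy(), "at_risk": at_risk})


# ---------------------------------------------------------------------------
# Log-rank (Mantel-Cox)


@dataclass
class LogrankResult:
    """Two-group Mantel-Cox test with the observed/expected hazard ratio."""

    chi2: float
    p: float
    hr: float
    hr_ci: tuple[float, float]
    observed: tuple[float, float]
    expected: tuple[float, float]
    n: tuple[int, int]
    degenerate: bool = False  # a group had zero events; HR one-sided

    def swap(self) -> "LogrankResult":
        """Result with group labels exchanged (HR becomes its reciprocal)."""
        lo, hi = self.hr_ci
        inv = lambda v: np.inf if v == 0 else (0.0 if np.isinf(v) else 1.0 / v)
        return LogrankResult(
            self.chi2, self.p, inv(self.hr), (inv(hi), inv(lo)),
            self.observed[::-1], self.expected[::-1], self.n[::-1], self.degenerate,
        )


def logrank_test(times1, events1, times2, events2) -> LogrankResult:
    """Mantel-Cox log-rank test between two strata.

    The chi-squared statistic is (O1 - E1)^2 / V with the hypergeometric
    variance V summed over distinct event times; the hazard ratio is
    (O1/E1)/(O2/E2) with CI exp(log HR +/- 1.96 * sqrt(1/E1 + 1/E2)).
    A stratum with zero events makes the HR degenerate (0 or inf); the CI
    is then one-sided and the result flagged.
    """
    t1, e1 = np.asarray(times1, float), np.asarray(events1, int)
    t2, e2 = np.asarray(times2, float), np.asarray(events2, int)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be nonempty")

    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    grp1 = np.concatenate([np.ones_like(t1, bool), np.zeros_like(t2, bool)])
    event_times = np.unique(all_t[all_e == 1])

    O1 = float(e1.sum())
    O2 = float(e2.sum())
    E1 = E2 = V = 0.0
    for t in event_times:
        at_risk = all_t >= t
        n = at_risk.sum()
        n1 = (at_risk & grp1).sum()
        d = int(all_e[(all_t == t)].sum())
        E1 += n1 * d / n
        E2 += (n - n1) * d / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)

    if V > 0:
        chi2 = (O1 - E1) ** 2 / V
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0

    se = np.sqrt(1.0 / E1 + 1.0 / E2) if E1 > 0 and E2 > 0 else np.nan
    degenerate = O1 == 0 or O2 == 0
    if O1 == 0 and O2 == 0:
        hr, ci = 1.0, (0.0, np.inf)
    elif O1 == 0:
        hr, ci = 0.0, (0.0, np.exp(np.log(max((O1 + 0.5) / E1 / ((O2 - 0.5) / E2), 1e-12)) + Z95 * se))
    elif O2 == 0:
        hr = np.inf
        ci = (np.exp(np.log((O1 - 0.5) / E1 / ((O2 + 0.5) / E2)) - Z95 * se), np.inf)
    else:
        hr = (O1 / E1) / (O2 / E2)
        ci = (float(np.exp(np.log(hr) - Z95 * se)), float(np.exp(np.log(hr) + Z95 * se)))
    return LogrankResult(
        chi2=float(chi2), p=p, hr=float(hr), hr_ci=ci,
        observed=(O1, O2), expected=(float(E1), float(E2)),
        n=(int(t1.size), int(t2.size)), degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


def cox_fit(times, events, covariates: pd.DataFrame) -> pd.DataFrame:
    """Cox proportional-hazards regression (Efron tie handling, Wald CIs).

    Returns one row per covariate with columns ``hr``, ``hr_lo``, ``hr_hi``,
    ``p`` and a ``converged`` flag shared across rows.

    Raises
    ------
    ValueError
        If the design matrix is rank-deficient (e.g. duplicated columns) or
        contains no events.
    """
    X = pd.DataFrame(covariates).astype(float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() < 1:
        raise ValueError("Cox regression requires at least one event")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    frame = X.copy()
    frame["_time"] = times
    frame["_event"] = events
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(frame, duration_col="_time", event_col="_event")
    summary = cph.summary
    out = pd.DataFrame(
        {
            "hr": summary["exp(coef)"],
            "hr_lo": summary["exp(coef) lower 95%"],
            "hr_hi": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    out["converged"] = True
    return out


# ---------------------------------------------------------------------------
# Fixed-horizon ROC


@dataclass
class ROCSummary:
    """Discrimination of a score for relapse-free status at a horizon.

    The positive class is "remained relapse-free"; higher scores predict it.
    ``sensitivity`` is the fraction of relapse-free patients with score above
    the signature cutoff, ``specificity`` the fraction of relapsed patients
    at or below it.
    """

    auc: float
    auc_ci: tuple[float, float]
    p: float
    horizon: float | None
    n_relapse_free: int
    n_relapsed: int
    n_excluded: int
    sensitivity: float
    specificity: float
    cutoff: float
    operating_points: pd.DataFrame = field(repr=False, default=None)


def roc_at_horizon(
    scores,
    times,
    events,
    horizon: float | None = None,
    cutoff: float = 0.0,
    censored_as_negative: bool = False,
) -> ROCSummary:
    """ROC analysis of a prognostic score against relapse by a horizon.

    A patient is "relapsed" if an event occurred at or before ``horizon``
    (any follow-up time when ``horizon`` is None). Patients censored before
    the horizon without an event carry no outcome label and are excluded by
    default (``censored_as_negative=True`` counts them relapse-free
    instead). AUC is the rank statistic P(score_free > score_relapsed) with
    ties at 1/2; its CI uses the Hanley-McNeil standard error and the p-value
    a normal test against AUC = 0.5.
    """
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if horizon is not None and horizon <= 0:
        raise ValueError("horizon must be positive")

    hz = np.inf if horizon is None else horizon
    relapsed = (events == 1) & (times <= hz)
    relapse_free = (times > hz) | ((events == 0) & np.isclose(times, hz)) if np.isfinite(hz) else (events == 0)
    undetermined = ~relapsed & ~relapse_free
    if censored_as_negative:
        relapse_free = relapse_free | undetermined
        undetermined = np.zeros_like(undetermined)

    keep = ~undetermined & ~np.isnan(scores)
    y_free = relapse_free[keep]
    s = scores[keep]
    n_pos, n_neg = int(y_free.sum()), int((~y_free).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("one outcome class is empty at this horizon")

    # Mann-Whitney formulation of the AUC; ties counted half.
    u = stats.mannwhitneyu(s[y_free], s[~y_free], alternative="two-sided")
    auc = float(u.statistic / (n_pos * n_neg))
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se = np.sqrt(
        max((auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg), 0.0)
    )
    ci = (max(0.0, auc - Z95 * se), min(1.0, auc + Z95 * se))
    p = float(2 * stats.norm.sf(abs(auc - 0.5) / se)) if se > 0 else (0.0 if auc != 0.5 else 1.0)

    grid = np.unique(s)
    ops = pd.DataFrame(
        {
            "cutoff": grid,
            "sensitivity": [float(np.mean(s[y_free] > c)) for c in grid],
            "specificity": [float(np.mean(s[~y_free] <= c)) for c in grid],
        }
    )
    return ROCSummary(
        auc=auc,
        auc_ci=ci,
        p=p,
        horizon=horizon,
        n_relapse_free=n_pos,
        n_relapsed=n_neg,
        n_excluded=int(undetermined.sum()),
        sensitivity=float(np.mean(s[y_free] > cutoff)),
        specificity=float(np.mean(s[~y_free] <= cutoff)),
        cutoff=cutoff,
        operating_points=ops,
    )


# ---------------------------------------------------------------------------
# Contingency, rank-based group comparison, correlation


def fisher_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def dunn_posthoc(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's pairwise z-tests on joint ranks with Bonferroni adjustment.

    Implemented here because no installed library ships Dunn's procedure;
    uses the tie-corrected variance of mean rank differences.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    rows = []
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    for a, b in pairs:
        se = np.sqrt(var_base * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p_raw})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p_raw"] * len(pairs), 1.0)
    return out


def group_compare(values, groups) -> dict:
    """Kruskal-Wallis across groups with Dunn's corrected pairwise tests.

    Returns ``{"kruskal_h", "kruskal_p", "pairwise"}``; with exactly two
    groups the pairwise table reduces to the single comparison.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must align")
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    h, p = stats.kruskal(*samples)
    return {"kruskal_h": float(h), "kruskal_p": float(p), "pairwise": dunn_posthoc(values, groups)}


def correlation_band(r: float) -> str:
    """Qualitative label: |r| < 0.4 weak, 0.4-0.7 moderate, > 0.7 strong."""
    a = abs(r)
    if a < 0.4:
        return "weak"
    if a <= 0.7:
        return "moderate"
    return "strong"


def score_correlation(x, y, method: str = "spearman") -> tuple[float, float, str]:
    """Correlation between two score vectors with a qualitative band.

    Rank (Spearman) correlation by default, consistent with the
    nonparametric treatment of IHC scores; ``method="pearson"`` available.
    Pairs with a missing value are dropped.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    if method == "spearman":
        r, p = stats.spearmanr(x[keep], y[keep])
    elif method == "pearson":
        r, p = stats.pearsonr(x[keep], y[keep])
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(r), float(p), correlation_band(float(r))
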