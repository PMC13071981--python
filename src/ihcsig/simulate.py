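"""Synthetic cohort and cell-table generation.

The real 293-patient anthracycline-treated cohort is not public, so this
module generates cohorts with the statistical structure the analysis
assumes: five St Gallen subtypes at the published prevalences, six
biomarker readouts drawn from subtype-dependent truncated-normal
distributions on their native scales (percent in [0, 100]; H-score in
[0, 100 * max_intensity]), completely-at-random missingness at the
published per-biomarker rates, and relapse times from an exponential
proportional-hazards model in which biomarker-high status multiplies the
subtype baseline hazard, with administrative censoring.

All randomness flows from a single seeded ``numpy`` Generator; the draw
order is fixed (subtype, ER/PR/HER2/Ki67 markers, biomarker scores,
missingness, relapse times), so identical config + seed reproduces the
table byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .biomarkers import (
    APPLICABLE_SUBTYPES,
    BIOMARKERS,
    PUBLISHED_HAZARD_RATIOS,
    SUBTYPES,
    BiomarkerSpec,
    default_panel,
)

#: Subtype counts in the modelled cohort (known-subtype denominator 287).
_SUBTYPE_COUNTS = {
    "LuminalA": 79,
    "LuminalB_HER2neg": 64,
    "LuminalB_HER2pos": 33,
    "HER2_enriched": 39,
    "TNBC": 72,
}
#: Relapse events per subtype over follow-up, used to set baseline hazards.
_SUBTYPE_EVENTS = {
    "LuminalA": 10,
    "LuminalB_HER2neg": 14,
    "LuminalB_HER2pos": 10,
    "HER2_enriched": 13,
    "TNBC": 22,
}

#: Score scale bounds per readout (percent vs 0-3 H-score).
SCORE_BOUNDS = {
    "TOP2A": (0.0, 100.0),
    "PTEN": (0.0, 300.0),
    "EGFR": (0.0, 300.0),
    "IGF1R": (0.0, 300.0),
    "pmTOR_wholecell": (0.0, 300.0),
    "pmTOR_perinuclear": (0.0, 100.0),
}

#: Per-biomarker missingness (fraction of 293 patients without a readout).
DEFAULT_MISSING_RATES = {
    "TOP2A": 20 / 293,
    "PTEN": 28 / 293,
    "EGFR": 22 / 293,
    "IGF1R": 25 / 293,
    "pmTOR_wholecell": 12 / 293,
    "pmTOR_perinuclear": 12 / 293,
}

#: Cutoffs defining "high" status inside the generator. Numeric published
#: thresholds are reused; EGFR's qualitative "extremely strong" rule is
#: represented by a fixed H-score near the 95th percentile of the non-
#: Luminal-A mixture under the default score distributions.
DEFAULT_GENERATIVE_THRESHOLDS = {
    "TOP2A": 45.0,
    "PTEN": 100.0,
    "EGFR": 150.0,
    "IGF1R": 219.0,
    "pmTOR_wholecell": 100.0,
    "pmTOR_perinuclear": 1.0,
}


@dataclass(frozen=True)
class SubtypeProfile:
    """Generative parameters for one molecular subtype.

    ``biomarker_params`` maps each readout to (location, scale) of a
    truncated normal on the readout's native scale; ``baseline_hazard`` is
    the exponential relapse rate (events/month) for a biomarker-low patient
    of this subtype.
    """

    name: str
    prevalence: float
    biomarker_params: dict[str, tuple[float, float]]
    baseline_hazard: float

    def __post_init__(self) -> None:
        if self.name not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.name!r}")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be a probability")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        for m, (_, scale) in self.biomarker_params.items():
            if scale <= 0:
                raise ValueError(f"scale for {m} must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator.

    ``effect_hrs`` multiply the hazard when a patient is biomarker-high
    (published per-readout hazard ratios by default; < 1 means high
    expression is protective). With ``restrict_effects`` each biomarker's
    effect acts only in its applicable subtypes. ``signature_hr``, when
    set, additionally multiplies the hazard for patients whose generative
    composite score is > 0 — a direct way to simulate a signature-level
    effect. Censoring is administrative at ``censoring_window`` months
    (a follow-up convention; the modelled study does not publish one).
    """

    n_patients: int
    seed: int
    effect_hrs: dict[str, float] = field(default_factory=lambda: dict(PUBLISHED_HAZARD_RATIOS))
    signature_hr: float | None = None
    restrict_effects: bool = True
    censoring_window: float = 120.0
    missing_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    unknown_marker_rate: float = 6 / 293
    generative_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENERATIVE_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(hr <= 0 for hr in self.effect_hrs.values()):
            raise ValueError("effect hazard ratios must be > 0")
        if self.signature_hr is not None and self.signature_hr <= 0:
            raise ValueError("signature_hr must be > 0")
        if any(not 0 <= r < 1 for r in self.missing_rates.values()):
            raise ValueError("missing rates must be in [0, 1)")
        if self.censoring_window <= 0:
            raise ValueError("censoring_window must be > 0")


def default_profiles(censoring_window: float = 120.0) -> list[SubtypeProfile]:
    """Profiles of the five subtypes under the modelled study's conditions.

    Prevalences are the published subtype counts over the 287 patients of
    known subtype. Baseline hazards are exponential rates reproducing each
    subtype's published relapse fraction over the censoring window. Score
    locations follow the published subtype ordering: TOP2A and EGFR highest
    in TNBC; PTEN and whole-cell p-mTOR lowest in TNBC; IGF1R highest in
    luminal disease; perinuclear p-mTOR flat across subtypes. Where a
    published cutoff is stated to be the median of its subtype group
    (PTEN 100, IGF1R 219), the group's generative median sits at that
    cutoff. Remaining locations/scales are a modelling choice (only box
    plots are published).
    """
    total = sum(_SUBTYPE_COUNTS.values())
    locs = {
        #              LumA   LumB-  LumB+  HER2   TNBC
        "TOP2A": (10.0, 20.0, 25.0, 38.0, 55.0),
        "PTEN": (150.0, 110.0, 100.0, 95.0, 70.0),
        "EGFR": (20.0, 35.0, 45.0, 65.0, 110.0),
        "IGF1R": (240.0, 219.0, 180.0, 120.0, 100.0),
        "pmTOR_wholecell": (130.0, 110.0, 100.0, 90.0, 60.0),
        "pmTOR_perinuclear": (1.5, 1.5, 1.5, 1.5, 1.5),
    }
    scales = {
        "TOP2A": 15.0,
        "PTEN": 40.0,
        "EGFR": 35.0,
        "IGF1R": 50.0,
        "pmTOR_wholecell": 35.0,
        "pmTOR_perinuclear": 1.5,
    }
    profiles = []
    for i, name in enumerate(SUBTYPES):
        frac_events = _SUBTYPE_EVENTS[name] / _SUBTYPE_COUNTS[name]
        baseline = -np.log(1 - frac_events) / censoring_window
        profiles.append(
            SubtypeProfile(
                name=name,
                prevalence=_SUBTYPE_COUNTS[name] / total,
                biomarker_params={m: (locs[m][i], scales[m]) for m in BIOMARKERS},
                baseline_hazard=float(baseline),
            )
        )
    return profiles


def _check_profiles(profiles: list[SubtypeProfile]) -> None:
    names = [p.name for p in profiles]
    if sorted(names) != sorted(SUBTYPES):
        raise ValueError("profiles must cover all five subtypes exactly once")
    total = sum(p.prevalence for p in profiles)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"prevalences must sum to 1 (got {total})")


def _truncnorm(rng, loc, scale, lo, hi, size):
    a = (lo - np.asarray(loc)) / scale
    b = (hi - np.asarray(loc)) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _subtype_markers(rng: np.random.Generator, subtype: np.ndarray) -> dict[str, np.ndarray]:
    """Draw ER/PR/HER2/Ki67 readouts consistent with each drawn subtype.

    Luminal disease receives ER+ staining (>= 1% nuclei, intensity 2-3) and
    PR+ in ~80% of cases; receptor-negative disease stays below the 1%
    positivity rule. Ki67 respects the 14% boundary of the Luminal A /
    Luminal B HER2-negative split, so subtype assignment from these markers
    round-trips to the subtype that generated them.
    """
    n = subtype.size
    luminal = np.isin(subtype, ["LuminalA", "LuminalB_HER2neg", "LuminalB_HER2pos"])

    er_percent = np.where(luminal, _truncnorm(rng, 80.0, 15.0, 1.0, 100.0, n), rng.uniform(0.0, 0.9, n))
    er_intensity = np.where(luminal, rng.integers(2, 4, n), rng.integers(0, 2, n))
    pr_pos = luminal & (rng.random(n) < 0.8)
    pr_percent = np.where(pr_pos, _truncnorm(rng, 60.0, 25.0, 1.0, 100.0, n), rng.uniform(0.0, 0.9, n))
    pr_intensity = np.where(pr_pos, rng.integers(1, 4, n), rng.integers(0, 2, n))

    ki67 = rng.uniform(20.0, 80.0, n)
    ki67 = np.where(subtype == "LuminalA", rng.uniform(2.0, 14.0, n), ki67)
    ki67 = np.where(subtype == "LuminalB_HER2neg", rng.uniform(14.5, 60.0, n), ki67)
    ki67 = np.where(subtype == "LuminalB_HER2pos", rng.uniform(5.0, 60.0, n), ki67)

    her2 = np.isin(subtype, ["LuminalB_HER2pos", "HER2_enriched"])
    return {
        "er_percent": np.round(er_percent, 2),
        "er_intensity": er_intensity.astype(int),
        "pr_percent": np.round(pr_percent, 2),
        "pr_intensity": pr_intensity.astype(int),
        "her2_positive": her2,
        "ki67_percent": np.round(ki67, 2),
    }


def simulate_cohort(
    config: SimulationConfig, profiles: list[SubtypeProfile] | None = None
) -> pd.DataFrame:
    """Generate a patient-level cohort table.

    Columns: ``patient_id`` (1-based), ``subtype_true``, the six subtype
    markers, the six biomarker readouts (NaN where missing), ``high_<m>``
    generative high flags, ``time_months`` and ``event`` (1 = relapse,
    0 = censored at the administrative window).
    """
    profiles = default_profiles(config.censoring_window) if profiles is None else profiles
    _check_profiles(profiles)
    by_name = {p.name: p for p in profiles}
    order = [p for p in profiles]
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    prev = np.array([p.prevalence for p in order])
    subtype = rng.choice([p.name for p in order], size=n, p=prev / prev.sum())

    cols: dict[str, np.ndarray] = {"patient_id": np.arange(1, n + 1), "subtype_true": subtype}
    cols.update(_subtype_markers(rng, subtype))

    # a small fraction of patients lack ER staining (unknown subtype)
    if config.unknown_marker_rate > 0:
        unknown = rng.random(n) < config.unknown_marker_rate
        cols["er_percent"] = np.where(unknown, np.nan, cols["er_percent"])
        cols["er_intensity"] = np.where(unknown, np.nan, cols["er_intensity"])

    for m in BIOMARKERS:
        lo, hi = SCORE_BOUNDS[m]
        loc = np.array([by_name[s].biomarker_params[m][0] for s in subtype])
        scale = np.array([by_name[s].biomarker_params[m][1] for s in subtype])
        cols[m] = np.round(_truncnorm(rng, loc, scale, lo, hi, n), 3)

    for m in BIOMARKERS:
        rate = config.missing_rates.get(m, 0.0)
        if rate > 0:
            cols[m] = np.where(rng.random(n) < rate, np.nan, cols[m])

    # generative high status and hazards
    high = {}
    comps = np.zeros(n, dtype=int)
    log_hr = np.zeros(n)
    for m in BIOMARKERS:
        thr = config.generative_thresholds[m]
        observed = ~np.isnan(cols[m])
        is_high = observed & (cols[m] >= thr)
        high[m] = is_high
        comps += np.where(observed, np.where(is_high, 1, -1), 0)
        applicable = (
            np.isin(subtype, list(APPLICABLE_SUBTYPES[m])) if config.restrict_effects else np.ones(n, bool)
        )
        log_hr += np.where(is_high & applicable, np.log(config.effect_hrs.get(m, 1.0)), 0.0)
    if config.signature_hr is not None:
        log_hr += np.where(comps > 0, np.log(config.signature_hr), 0.0)

    baseline = np.array([by_name[s].baseline_hazard for s in subtype])
    lam = baseline * np.exp(log_hr)
    t_event = rng.exponential(1.0 / lam)
    event = t_event <= config.censoring_window
    time = np.minimum(t_event, config.censoring_window)

    for m in BIOMARKERS:
        cols[f"high_{m}"] = high[m]
    cols["time_months"] = np.round(time, 3)
    cols["event"] = event.astype(int)
    return pd.DataFrame(cols)


def simulate_cells(
    n_cells: int,
    tumour_fraction: float,
    intensity_mix,
    seed: int,
    spec: BiomarkerSpec | None = None,
    patient_id: int = 1,
    core_id: str = "core_1",
) -> pd.DataFrame:
    """Generate one core's cell table with a prescribed intensity mixture.

    ``intensity_mix`` gives the expected proportions of tumour cells at
    intensities 0..max_intensity (length max_intensity + 1). Each cell's
    optical density is drawn uniformly within the spec's right-open density
    bin for its intensity (the top bin extends one bin-width above the last
    threshold), so re-binning by the scoring rules recovers the mixture
    exactly in expectation. The same density is written to every
    compartment column, making the mixture hold at any localisation.
    Stromal cells are drawn from the same mixture; scoring excludes them
    anyway.
    """
    spec = default_panel()["TOP2A"] if spec is None else spec
    mix = np.asarray(intensity_mix, float)
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if not 0 <= tumour_fraction <= 1:
        raise ValueError("tumour_fraction must be a probability")
    if mix.size != spec.max_intensity + 1 or np.any(mix < 0) or abs(mix.sum() - 1) > 1e-9:
        raise ValueError("intensity_mix must be non-negative proportions over "
                         f"{spec.max_intensity + 1} intensities summing to 1")

    rng = np.random.default_rng(seed)
    if n_cells == 0:
        return pd.DataFrame(columns=list(("patient_id", "core_id", "cell_class") +
                                         ("od_nuclear", "od_cytoplasm", "od_perinuclear", "od_cell")))
    bins = np.array(spec.od_bins)
    width = bins[-1] - bins[-2] if bins.size > 1 else bins[0]
    edges = np.concatenate([[0.0], bins, [bins[-1] + width]])
    intensity = rng.choice(spec.max_intensity + 1, size=n_cells, p=mix)
    od = rng.uniform(edges[intensity], edges[intensity + 1])
    tumour = rng.random(n_cells) < tumour_fraction
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "core_id": core_id,
            "cell_class": np.where(tumour, "tumour", "stroma"),
            "od_nuclear": np.round(od, 4),
            "od_cytoplasm": np.round(od, 4),
            "od_perinuclear": np.round(od, 4),
            "od_cell": np.round(od, 4),
        }
    )
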