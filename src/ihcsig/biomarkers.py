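"""Biomarker panel definitions.

The panel comprises six readouts of five proteins: TOP2A (nuclear),
PTEN (nuclear), EGFR (whole cell), IGF1R (whole cell) and phospho-mTOR
scored both over the whole cell and restricted to the perinuclear region
(the latter reflecting mTORC1-complex localisation). TOP2A and
perinuclear p-mTOR stain homogeneously and are scored as percent
positive tumour cells; the rest stain heterogeneously and are scored by
H-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical readout names, in signature order.
BIOMARKERS: tuple[str, ...] = (
    "TOP2A",
    "PTEN",
    "EGFR",
    "IGF1R",
    "pmTOR_wholecell",
    "pmTOR_perinuclear",
)

#: Subtype labels (St Gallen surrogate classes).
SUBTYPES: tuple[str, ...] = (
    "LuminalA",
    "LuminalB_HER2neg",
    "LuminalB_HER2pos",
    "HER2_enriched",
    "TNBC",
)
UNKNOWN_SUBTYPE = "Unknown"

LOCALISATIONS = ("nuclear", "wholecell", "perinuclear")
METHODS = ("percent_positive", "h_score")

#: Maps a staining localisation to the optical-density column of a cell table.
LOCALISATION_COLUMNS = {
    "nuclear": "od_nuclear",
    "wholecell": "od_cell",
    "perinuclear": "od_perinuclear",
}


@dataclass(frozen=True)
class BiomarkerSpec:
    """How one biomarker readout is scored from per-cell optical densities.

    Parameters
    ----------
    name : str
        Readout name (one of :data:`BIOMARKERS` for the shipped panel).
    localisation : str
        Subcellular compartment whose DAB optical density is read:
        ``nuclear``, ``wholecell`` or ``perinuclear``.
    method : str
        ``percent_positive`` (fraction of tumour cells with intensity >= 1)
        or ``h_score`` (intensity-weighted percentage sum).
    max_intensity : int
        Top of the ordinal intensity scale (3 or 4).
    od_bins : tuple of float
        Strictly ascending optical-density thresholds; a density lying at or
        above the k-th threshold scores at least intensity k (right-open
        bins). Length must equal ``max_intensity``.
    """

    name: str
    localisation: str
    method: str
    max_intensity: int = 3
    od_bins: tuple[float, ...] = (0.2, 0.4, 0.6)

    def __post_init__(self) -> None:
        if self.localisation not in LOCALISATIONS:
            raise ValueError(f"unknown localisation {self.localisation!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown scoring method {self.method!r}")
        if self.max_intensity not in (3, 4):
            raise ValueError("max_intensity must be 3 or 4")
        if len(self.od_bins) != self.max_intensity:
            raise ValueError("od_bins length must equal max_intensity")
        if any(b <= a for a, b in zip(self.od_bins, self.od_bins[1:])):
            raise ValueError("od_bins must be strictly ascending")
        if self.od_bins[0] <= 0:
            raise ValueError("od_bins must be positive")

    @property
    def od_column(self) -> str:
        return LOCALISATION_COLUMNS[self.localisation]

    @property
    def max_score(self) -> float:
        """Upper bound of the score scale (100 or 100 * max_intensity)."""
        return 100.0 if self.method == "percent_positive" else 100.0 * self.max_intensity


def default_panel() -> dict[str, BiomarkerSpec]:
    """The shipped six-readout panel.

    Localisation and scoring method per readout: TOP2A and perinuclear
    p-mTOR by percent positive (homogeneous staining), PTEN / EGFR / IGF1R /
    whole-cell p-mTOR by H-score. Optical-density bins default to
    (0.2, 0.4, 0.6) on a 0-3 scale; both are config-overridable since DAB
    thresholds are an imaging-workflow convention, not a published constant.
    """
    return {
        "TOP2A": BiomarkerSpec("TOP2A", "nuclear", "percent_positive"),
        "PTEN": BiomarkerSpec("PTEN", "nuclear", "h_score"),
        "EGFR": BiomarkerSpec("EGFR", "wholecell", "h_score"),
        "IGF1R": BiomarkerSpec("IGF1R", "wholecell", "h_score"),
        "pmTOR_wholecell": BiomarkerSpec("pmTOR_wholecell", "wholecell", "h_score"),
        "pmTOR_perinuclear": BiomarkerSpec("pmTOR_perinuclear", "perinuclear", "percent_positive"),
    }


#: Subtype sets in which each readout showed a survival association and is
#: therefore part of the published signature (the "applicability" sets).
#: TOP2A: ER-negative disease; PTEN: HER2-positive plus Luminal B HER2-negative;
#: EGFR: everything except Luminal A; IGF1R: Luminal B HER2-negative;
#: whole-cell p-mTOR: Luminal B; perinuclear p-mTOR: HER2-positive.
APPLICABLE_SUBTYPES: dict[str, frozenset[str]] = {
    "TOP2A": frozenset({"HER2_enriched", "TNBC"}),
    "PTEN": frozenset({"LuminalB_HER2neg", "LuminalB_HER2pos", "HER2_enriched"}),
    "EGFR": frozenset({"LuminalB_HER2neg", "LuminalB_HER2pos", "HER2_enriched", "TNBC"}),
    "IGF1R": frozenset({"LuminalB_HER2neg"}),
    "pmTOR_wholecell": frozenset({"LuminalB_HER2neg", "LuminalB_HER2pos"}),
    "pmTOR_perinuclear": frozenset({"LuminalB_HER2pos", "HER2_enriched"}),
}

#: Published high/low cutoffs. EGFR's published rule is qualitative
#: ("extremely strong staining"); it is operationalised as the 95th percentile
#: of the non-Luminal-A cohort and therefore has no fixed value here.
PUBLISHED_THRESHOLDS: dict[str, float] = {
    "TOP2A": 45.0,
    "PTEN": 100.0,
    "IGF1R": 219.0,
    "pmTOR_wholecell": 100.0,
    "pmTOR_perinuclear": 1.0,
}

#: Quantile of the non-Luminal-A score distribution used to operationalise
#: EGFR's "extremely strong staining" cutoff.
EGFR_EXTREME_QUANTILE = 0.95

#: Published per-readout hazard ratios (high vs low expression, relapse-free
#: survival) within each readout's applicable subtype group.
PUBLISHED_HAZARD_RATIOS: dict[str, float] = {
    "TOP2A": 0.287,
    "PTEN": 0.356,
    "EGFR": 0.2979,
    "IGF1R": 0.2816,
    "pmTOR_wholecell": 0.3832,
    "pmTOR_perinuclear": 0.2977,
}
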