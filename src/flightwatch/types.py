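"""Core domain containers shared across the pipeline.

The analysis grain throughout is the *unit*: one species in one 1-degree
grid cell in one year.  Grid cells are 1-degree tiles keyed as
``"{floor(lat)}_{floor(lon)}"``; day-of-year (DOY) is 1-based (Jan 1 = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

OVERWINTER_CLASSES = ("egg", "larva", "pupa", "adult", "migrant")


@dataclass
class SpeciesTraits:
    """Life-history and observability traits for one species.

    ``overwinter_class`` is the stage in which residents pass winter
    (egg/larva/pupa/adult); migrants overwinter outside the study region.
    ``detectability`` scales every observation process; ``confusability``
    is the propensity to be mistaken for a look-alike species.
    """

    species_id: str
    overwinter_class: str
    voltinism: int
    host_breadth: str  # "specialist" | "generalist"
    locally_common: int  # 0/1
    wing_size: float  # mm
    mobility: int  # ordinal 1..5
    canopy_assoc: int  # 0/1
    egg_cluster: int  # 0/1
    detectability: float  # (0, 1]
    confusability: float  # [0, 1)

    def __post_init__(self) -> None:
        if self.overwinter_class not in OVERWINTER_CLASSES:
            raise ValueError(
                f"overwinter_class must be one of {OVERWINTER_CLASSES}, "
                f"got {self.overwinter_class!r}"
            )
        if self.voltinism < 1:
            raise ValueError("voltinism must be >= 1")
        if not 0 < self.detectability <= 1:
            raise ValueError("detectability must be in (0, 1]")
        if not 0 <= self.confusability < 1:
            raise ValueError("confusability must be in [0, 1)")


@dataclass
class TruePhenology:
    """Ground-truth flight-curve parameters for one species-cell-year.

    The within-season adult activity curve is a Gaussian mixture with one
    component per generation; ``true_doy10``/``true_doy50`` are the exact
    10% and 50% quantiles of that mixture.
    """

    species_id: str
    cell_id: str
    year: int
    generation_means: list[float]
    generation_sds: list[float]
    generation_weights: list[float]
    true_doy10: float
    true_doy50: float
    seasonal_total: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.generation_weights, dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("generation_weights must sum to 1")
        if any(s <= 0 for s in self.generation_sds):
            raise ValueError("generation_sds must be positive")
        if self.true_doy10 > self.true_doy50 + 1e-9:
            raise ValueError("true_doy10 must be <= true_doy50")


@dataclass
class SurveyDesign:
    """Program-level transect survey design for the synthetic generator."""

    n_sites_per_cell: int = 5
    season_start_doy: int = 152  # many programs need not start before ~June 1
    season_end_doy: int = 273
    visit_interval_days: int = 7
    site_abundance_multipliers: list[float] | None = None

    def __post_init__(self) -> None:
        if self.season_start_doy >= self.season_end_doy:
            raise ValueError("season_start_doy must be < season_end_doy")
        if self.site_abundance_multipliers is not None and any(
            m <= 0 for m in self.site_abundance_multipliers
        ):
            raise ValueError("site abundance multipliers must be > 0")


@dataclass
class FlightCurve:
    """Normalized within-season activity density over day-of-year."""

    species_id: str
    cell_id: str
    year: int
    doy_grid: np.ndarray  # integer DOYs, daily resolution
    density: np.ndarray  # nonnegative, trapezoid-integrates to 1
    cumulative: np.ndarray  # CDF over doy_grid, 0 -> 1

    def __post_init__(self) -> None:
        self.doy_grid = np.asarray(self.doy_grid)
        self.density = np.asarray(self.density, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if (self.density < -1e-12).any():
            raise ValueError("density must be nonnegative")
        if (np.diff(self.cumulative) < -1e-9).any():
            raise ValueError("cumulative must be non-decreasing")


@dataclass
class Phenometric:
    """An estimated percentile DOY with bootstrap CI and effort metadata."""

    species_id: str
    cell_id: str
    year: int
    source: str  # "survey" | "incidental"
    percentile: int  # 10 | 50
    doy_estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_surveys: int = 0
    n_sites: int = 0
    n_positive_surveys: int = 0
    n_records: int = 0
    flagged: bool = False

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low


@dataclass
class LmmFit:
    """Summary of a fitted random-intercept linear mixed model."""

    formula: str
    method: str  # "ML" | "REML"
    params: dict = field(default_factory=dict)
    bse: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)  # approximate (residual-df t)
    sigma2_species: float = float("nan")
    sigma2_resid: float = float("nan")
    vc_components: dict = field(default_factory=dict)
    loglik: float = float("nan")
    aic: float = float("nan")  # always from the ML likelihood
    n_obs: int = 0
    n_species: int = 0
    n_params: int = 0
    r2_marginal: float = float("nan")
    r2_conditional: float = float("nan")
    converged: bool = True
    result: object = None  # underlying statsmodels results object


def cell_id_from_lonlat(lon: float, lat: float) -> str:
    """1-degree tile key: floor(lat), floor(lon)."""
    return f"{int(np.floor(lat))}_{int(np.floor(lon))}"
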