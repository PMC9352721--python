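"""Synthetic data with the statistical structure the pipeline assumes.

Generates, per 1-degree grid cell: a daily climate series, a species pool
with life-history traits, ground-truth flight curves (Gaussian mixtures,
one component per generation, first-generation timing driven by log
degree-days and overwinter stage plus a species random intercept),
Pollard-style transect survey counts (shared within-cell phenology,
site-varying abundance, explicit zeros), and presence-only incidental
records thinned by an observer-effort model.  A truth table supports
parameter-recovery tests downstream.

All generators are deterministic given (config, seed); child streams are
spawned from a single ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import OVERWINTER_CLASSES, SpeciesTraits, SurveyDesign, TruePhenology

# ---------------------------------------------------------------------------
# truth coefficients


@dataclass
class CoefTruth:
    """True fixed/random-effect structure behind simulated emergence timing.

    First-generation mean DOY for species s in cell-year u is
    ``stage_intercept[ow(s)] + slope_log_gdd * log(GDD_u) + alpha_s + eps_u``
    with ``alpha_s ~ N(0, sigma_species^2)`` and unit noise
    ``eps_u ~ N(0, sigma_unit^2)``.

    Default magnitudes give midsummer flight at typical accumulations of
    600-1200 degree-days, stage ordering adult < pupa < larva < egg <
    migrant (later overwinter stages need less post-winter development;
    migrants arrive last), and a moderately strong negative temperature
    effect.
    """

    stage_intercepts: dict = field(default_factory=lambda: {
        "adult": 354.0, "pupa": 382.0, "larva": 399.0,
        "egg": 410.0, "migrant": 432.0,
    })
    slope_log_gdd: float = -30.0
    sigma_species: float = 8.0
    sigma_unit: float = 10.0
    generation_gap_days: float = 45.0
    generation_sd: float = 10.0
    generation_weight_decay: float = 0.6

    def __post_init__(self) -> None:
        if self.sigma_species < 0:
            raise ValueError("species random-intercept sd must be >= 0")
        if self.sigma_unit < 0:
            raise ValueError("unit noise sd must be >= 0")


# ---------------------------------------------------------------------------
# climate


@dataclass
class ClimateParams:
    """Sinusoidal annual temperature cycle with daily noise.

    ``annual_mean``/``amplitude`` are C; the cycle peaks at
    ``peak_doy``; ``diurnal_range`` separates tmin and tmax around the
    daily mean; ``noise_sd`` perturbs the daily mean (tmin and tmax move
    together, so tmin <= tmax always); ``cell_offsets`` shift whole cells
    (e.g. a latitudinal gradient).
    """

    annual_mean: float = 12.0
    amplitude: float = 14.0
    peak_doy: float = 200.0
    diurnal_range: float = 10.0
    noise_sd: float = 2.0
    cell_offsets: dict = field(default_factory=dict)
    lat_ref: float = 38.0  # latitude at which offset is 0
    lat_gradient: float = -1.0  # C per degree latitude northward

    def __post_init__(self) -> None:
        if self.diurnal_range <= 0:
            raise ValueError("diurnal range must be positive")


def cell_key(cell) -> str:
    lat, lon = cell
    return f"{int(lat)}_{int(lon)}"


def generate_climate(cells, years, climate_params: ClimateParams,
                     seed: int) -> pd.DataFrame:
    """Daily tmin/tmax per cell: columns cell_id, date, tmin, tmax."""
    rng = np.random.default_rng(seed)
    p = climate_params
    frames = []
    for cell in cells:
        cid = cell_key(cell)
        lat = float(cell[0])
        offset = (p.lat_gradient * (lat - p.lat_ref)
                  + p.cell_offsets.get(cid, 0.0))
        for year in years:
            dates = pd.date_range(dt.date(year, 1, 1), dt.date(year, 12, 31),
                                  freq="D")
            doy = dates.dayofyear.to_numpy(dtype=float)
            n_days = len(dates)
            tmean = (p.annual_mean + offset
                     + p.amplitude * np.cos(2 * np.pi * (doy - p.peak_doy)
                                            / n_days)
                     + rng.normal(0.0, p.noise_sd, size=len(doy)))
            frames.append(pd.DataFrame({
                "cell_id": cid,
                "date": dates.strftime("%Y-%m-%d"),
                "tmin": tmean - p.diurnal_range / 2.0,
                "tmax": tmean + p.diurnal_range / 2.0,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# species pool


def generate_species_pool(n_species: int, coef_truth: CoefTruth,
                          seed: int) -> tuple[list[SpeciesTraits], pd.DataFrame]:
    """Species traits plus the per-species true random intercepts.

    Overwinter classes are assigned round-robin so that every class is
    represented whenever ``n_species >= 5``.  Returns (traits list, frame
    of true coefficients with columns species_id, overwinter_class,
    alpha_species).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    traits: list[SpeciesTraits] = []
    alphas = rng.normal(0.0, coef_truth.sigma_species, size=n_species)
    for i in range(n_species):
        ow = OVERWINTER_CLASSES[i % len(OVERWINTER_CLASSES)]
        voltinism = 1 if ow == "egg" else int(rng.choice([1, 1, 2, 2, 3]))
        traits.append(SpeciesTraits(
            species_id=f"sp{i:03d}",
            overwinter_class=ow,
            voltinism=voltinism,
            host_breadth=str(rng.choice(["specialist", "generalist"])),
            locally_common=int(rng.random() < 0.5),
            wing_size=float(np.round(rng.lognormal(np.log(40), 0.3), 1)),
            mobility=int(rng.integers(1, 6)),
            canopy_assoc=int(rng.random() < 0.3),
            egg_cluster=int(rng.random() < 0.2),
            detectability=float(np.round(rng.uniform(0.4, 1.0), 3)),
            confusability=float(np.round(rng.uniform(0.0, 0.6), 3)),
        ))
    coef = pd.DataFrame({
        "species_id": [t.species_id for t in traits],
        "overwinter_class": [t.overwinter_class for t in traits],
        "alpha_species": alphas,
    })
    return traits, coef


def traits_frame(traits: list[SpeciesTraits]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in traits])


# ---------------------------------------------------------------------------
# true phenology (Gaussian-mixture flight curves)


def mixture_cdf(x, means, sds, weights):
    x = np.asarray(x, dtype=float)[..., None]
    return np.sum(np.asarray(weights)
                  * stats.norm.cdf(x, loc=means, scale=sds), axis=-1)


def mixture_pdf(x, means, sds, weights):
    x = np.asarray(x, dtype=float)[..., None]
    return np.sum(np.asarray(weights)
                  * stats.norm.pdf(x, loc=means, scale=sds), axis=-1)


def mixture_quantile(p: float, means, sds, weights) -> float:
    """Numeric inversion of the Gaussian-mixture CDF (brentq)."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    lo = float(np.min(means - 8 * sds))
    hi = float(np.max(means + 8 * sds))
    return float(optimize.brentq(
        lambda x: mixture_cdf(x, means, sds, weights) - p, lo, hi,
        xtol=1e-6))


def simulate_true_phenology(traits, gdd_by_cell_year: pd.DataFrame,
                            coef_truth: CoefTruth, seed: int,
                            abundance_params=None) -> list[TruePhenology]:
    """Ground-truth flight curve per species-cell-year.

    ``gdd_by_cell_year`` has columns cell_id, year, gdd (all > 0).  The
    first-generation mean follows the linear log-GDD / overwinter-stage
    model of :class:`CoefTruth`; later generations are displaced by the
    generation gap with geometrically decaying weights.  True 10%/50%
    quantiles come from numeric inversion of the mixture CDF.

    Seasonal total abundance is lognormal; "locally common" species get a
    higher median (abundance_params = dict(median_common, median_rare,
    sigma_log)).
    """
    rng = np.random.default_rng(seed)
    ab = {"median_common": 800.0, "median_rare": 250.0, "sigma_log": 0.5}
    if abundance_params:
        ab.update(abundance_params)
    coef_map = None
    if isinstance(traits, tuple):  # (traits, coef) convenience
        traits, coef_map = traits
    if coef_map is None:
        raise ValueError("pass (traits, coef_frame) from generate_species_pool")
    alpha = dict(zip(coef_map["species_id"], coef_map["alpha_species"]))

    out: list[TruePhenology] = []
    for t in traits:
        for _, row in gdd_by_cell_year.iterrows():
            if not np.isfinite(row["gdd"]) or row["gdd"] <= 0:
                import warnings
                warnings.warn(
                    f"missing/invalid GDD for {row['cell_id']} "
                    f"{row['year']}; unit skipped")
                continue
            mu1 = (coef_truth.stage_intercepts[t.overwinter_class]
                   + coef_truth.slope_log_gdd * np.log(row["gdd"])
                   + alpha[t.species_id]
                   + rng.normal(0.0, coef_truth.sigma_unit))
            v = t.voltinism
            means = [mu1 + g * coef_truth.generation_gap_days
                     for g in range(v)]
            sds = [coef_truth.generation_sd] * v
            w = coef_truth.generation_weight_decay ** np.arange(v)
            w = (w / w.sum()).tolist()
            median = (ab["median_common"] if t.locally_common
                      else ab["median_rare"])
            total = float(rng.lognormal(np.log(median), ab["sigma_log"]))
            out.append(TruePhenology(
                species_id=t.species_id, cell_id=row["cell_id"],
                year=int(row["year"]), generation_means=means,
                generation_sds=sds, generation_weights=w,
                true_doy10=mixture_quantile(0.10, means, sds, w),
                true_doy50=mixture_quantile(0.50, means, sds, w),
                seasonal_total=total,
            ))
    return out


def truth_frame(truth: list[TruePhenology]) -> pd.DataFrame:
    rows = []
    for t in truth:
        rows.append({
            "species_id": t.species_id, "cell_id": t.cell_id, "year": t.year,
            "true_doy10": t.true_doy10, "true_doy50": t.true_doy50,
            "seasonal_total": t.seasonal_total,
            "generation_means": ";".join(f"{m:.3f}" for m in t.generation_means),
            "generation_sds": ";".join(f"{s:.3f}" for s in t.generation_sds),
            "generation_weights": ";".join(
                f"{w:.6f}" for w in t.generation_weights),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survey observation process


def _doy_to_date(year: int, doy: int) -> str:
    return (dt.date(year, 1, 1) + dt.timedelta(days=int(doy) - 1)).isoformat()


def simulate_surveys(truth: list[TruePhenology], design: SurveyDesign,
                     traits, seed: int) -> pd.DataFrame:
    """Pollard-style transect counts; absences (zeros) are recorded.

    Visits happen at fixed intervals within the survey season at every
    site of a cell; the count of species s at site i on day d is
    Poisson(site multiplier x seasonal total x flight-curve density(d) x
    detectability).  Columns: site_id, date, species_id, count, cell_id.
    """
    rng = np.random.default_rng(seed)
    det = {t.species_id: t.detectability for t in traits}
    mult = design.site_abundance_multipliers
    if mult is None:
        mult_by_cell: dict[str, np.ndarray] = {}
    else:
        mult = np.asarray(mult, dtype=float)

    doys = np.arange(design.season_start_doy, design.season_end_doy + 1,
                     design.visit_interval_days)
    by_cell_year: dict[tuple, list[TruePhenology]] = {}
    for t in truth:
        by_cell_year.setdefault((t.cell_id, t.year), []).append(t)

    rows = []
    for (cell, year), units in sorted(by_cell_year.items()):
        if mult is None:
            if cell not in mult_by_cell:
                mult_by_cell[cell] = rng.lognormal(
                    0.0, 0.5, size=design.n_sites_per_cell)
            m = mult_by_cell[cell]
        else:
            m = mult
        for site_i, site_mult in enumerate(m):
            site_id = f"{cell}_site{site_i:02d}"
            for doy in doys:
                date = _doy_to_date(year, doy)
                for u in sorted(units, key=lambda u: u.species_id):
                    lam = (site_mult * u.seasonal_total
                           * mixture_pdf(float(doy), u.generation_means,
                                         u.generation_sds,
                                         u.generation_weights)
                           * det[u.species_id])
                    rows.append({
                        "site_id": site_id, "date": date,
                        "species_id": u.species_id,
                        "count": int(rng.poisson(float(lam))),
                        "cell_id": cell,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# incidental observation process


@dataclass
class EffortModel:
    """Observer effort over day-of-year: seasonal ramp x weekend uplift.

    ``ramp`` is a piecewise-linear (doy, weight) polyline; weekends get
    ``weekend_multiplier`` x effort, emulating the recreational-reporting
    bias of incidental platforms.  ``base_rate`` scales the expected
    record count per unit at full effort and detectability 1.
    """

    ramp: list = field(default_factory=lambda: [(1, 0.3), (150, 1.0),
                                                (365, 1.0)])
    weekend_multiplier: float = 2.0
    base_rate: float = 60.0

    def weight(self, doy, year: int):
        doy = np.atleast_1d(np.asarray(doy, dtype=float))
        xs = [x for x, _ in self.ramp]
        ys = [y for _, y in self.ramp]
        w = np.interp(doy, xs, ys)
        # weekday of each doy in this year
        jan1 = dt.date(year, 1, 1).weekday()  # Mon=0
        wd = (jan1 + doy.astype(int) - 1) % 7
        w = np.where(wd >= 5, w * self.weekend_multiplier, w)
        return w

    @classmethod
    def flat(cls, base_rate: float = 60.0) -> "EffortModel":
        return cls(ramp=[(1, 1.0), (365, 1.0)], weekend_multiplier=1.0,
                   base_rate=base_rate)


def simulate_incidental(truth: list[TruePhenology], effort_model: EffortModel,
                        traits, seed: int,
                        confusable_pairs=None) -> pd.DataFrame:
    """Presence-only records: thinned inhomogeneous daily point process.

    Record intensity on day d is base_rate x curve density(d) x effort(d)
    x detectability; no zeros are emitted.  Coordinates are uniform within
    the unit's 1-degree cell.  ``confusable_pairs`` optionally enables
    label swaps between designated look-alike species at the reporting
    species' confusability rate (off by default).
    Columns: species_id, date, lon, lat, platform, cell_id.
    """
    rng = np.random.default_rng(seed)
    det = {t.species_id: t.detectability for t in traits}
    conf = {t.species_id: t.confusability for t in traits}
    swap = {}
    if confusable_pairs:
        for a, b in confusable_pairs:
            swap[a], swap[b] = b, a

    all_doys = np.arange(1, 366)
    rows = []
    for u in sorted(truth, key=lambda u: (u.cell_id, u.year, u.species_id)):
        eff = effort_model.weight(all_doys, u.year)
        if not np.any(eff > 0):
            import warnings
            warnings.warn("all-zero effort; no incidental records generated")
            continue
        dens = mixture_pdf(all_doys.astype(float), u.generation_means,
                           u.generation_sds, u.generation_weights)
        lam = effort_model.base_rate * dens * eff * det[u.species_id]
        counts = rng.poisson(lam)
        lat0, lon0 = (int(s) for s in u.cell_id.split("_"))
        for doy, k in zip(all_doys[counts > 0], counts[counts > 0]):
            for _ in range(int(k)):
                sp = u.species_id
                if sp in swap and rng.random() < conf[sp]:
                    sp = swap[sp]
                rows.append({
                    "species_id": sp,
                    "date": _doy_to_date(u.year, int(doy)),
                    "lon": float(np.round(lon0 + rng.random(), 5)),
                    "lat": float(np.round(lat0 + rng.random(), 5)),
                    "platform": str(rng.choice(
                        ["iNaturalist", "eButterfly"], p=[0.8, 0.2])),
                    "cell_id": u.cell_id,
                })
    cols = ["species_id", "date", "lon", "lat", "platform", "cell_id"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# direct regression-frame simulation (for mixed-model recovery studies)


def simulate_model_frame(n_units: int, n_species: int,
                         coef_truth: CoefTruth, seed: int,
                         gdd_range=(500.0, 1500.0)) -> pd.DataFrame:
    """Regression frame drawn directly from the emergence-timing model.

    Response ``doy`` = stage intercept + slope * log(GDD) + species
    intercept + unit noise, with GDD uniform on ``gdd_range``.  Includes a
    pure-noise covariate ``noise_cov`` for AIC-selection studies.  Used
    for parameter-recovery experiments where the observation layer is not
    under study.
    """
    rng = np.random.default_rng(seed)
    sp = np.repeat(np.arange(n_species),
                   int(np.ceil(n_units / n_species)))[:n_units]
    alpha = rng.normal(0.0, coef_truth.sigma_species, n_species)
    ow = np.array(OVERWINTER_CLASSES)[sp % len(OVERWINTER_CLASSES)]
    log_gdd = np.log(rng.uniform(*gdd_range, size=n_units))
    doy = (np.array([coef_truth.stage_intercepts[o] for o in ow])
           + coef_truth.slope_log_gdd * log_gdd
           + alpha[sp]
           + rng.normal(0.0, coef_truth.sigma_unit, n_units))
    return pd.DataFrame({
        "species_id": [f"sp{i:03d}" for i in sp],
        "overwinter_class": ow,
        "log_gdd": log_gdd,
        "doy": doy,
        "noise_cov": rng.normal(size=n_units),
    })


# ---------------------------------------------------------------------------
# day-0 references (simulation-mode stand-in for field-guide onset dates)


def make_day0_references(truth: list[TruePhenology],
                         region: str = "all") -> pd.DataFrame:
    """Guide-like onset per species: the earliest true 10% DOY across the
    species' units, rounded (field guides report typical flight
    *initiation*, which precedes most units' 10% metric); day0 = onset - 7.
    Synthetic stand-in for regional field-guide digitization."""
    df = truth_frame(truth)
    onset = (df.groupby("species_id")["true_doy10"].min().round()
             .astype(int).rename("guide_onset_doy").reset_index())
    onset["region"] = region
    onset["day0"] = onset["guide_onset_doy"] - 7
    return onset[["species_id", "region", "guide_onset_doy", "day0"]]
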