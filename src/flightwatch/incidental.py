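"""Percentile phenometrics from presence-only occurrence records.

Presence-only reports carry no effort or absence information, so the
flight-curve machinery of the survey stream does not apply; instead the
10%/50% day-of-year phenometrics are empirical quantiles of the record
DOYs, which remain unbiased when flight periods span multiple generations.
Confidence intervals come from resampling records with replacement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import Phenometric, cell_id_from_lonlat

MIN_RECORDS = 10  # unit eligibility threshold


def assign_cells(records: pd.DataFrame) -> pd.DataFrame:
    """Derive cell_id from lon/lat (1-degree floor tiles) where missing."""
    df = records.copy()
    if "cell_id" not in df.columns:
        df["cell_id"] = [cell_id_from_lonlat(lo, la)
                         for lo, la in zip(df["lon"], df["lat"])]
    return df


def deduplicate_occurrences(records: pd.DataFrame) -> pd.DataFrame:
    """Drop cross-platform duplicates: same species, date, lon and lat
    (full stored precision) keep only the first record.  Idempotent."""
    return records.drop_duplicates(
        subset=["species_id", "date", "lon", "lat"], keep="first"
    ).reset_index(drop=True)


def filter_incidental_units(records: pd.DataFrame) -> pd.DataFrame:
    """Eligible (species_id, cell_id, year) units: >= MIN_RECORDS records.
    Input should already be deduplicated."""
    df = assign_cells(records)
    df["year"] = pd.to_datetime(df["date"]).dt.year
    counts = (df.groupby(["species_id", "cell_id", "year"])
              .size().rename("n_records").reset_index())
    out = counts[counts["n_records"] >= MIN_RECORDS]
    return out[["species_id", "cell_id", "year"]].reset_index(drop=True)


def quantile_doy(doys, p: float) -> float:
    """Empirical p% quantile of record DOYs, linear interpolation of order
    statistics (numpy's default convention).  Monotone in p and shift-
    equivariant."""
    doys = np.asarray(doys, dtype=float)
    if doys.size == 0:
        raise ValueError("no DOYs supplied")
    return float(np.quantile(doys, p / 100.0, method="linear"))


def bootstrap_incidental_phenometric(doys, p: float, B: int = 500,
                                     seed: int = 0, level: float = 0.95
                                     ) -> Phenometric:
    """Quantile phenometric with a record-resampling bootstrap CI."""
    if B < 2:
        raise ValueError("B must be >= 2")
    doys = np.asarray(doys, dtype=float)
    est = quantile_doy(doys, p)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, doys.size, size=(B, doys.size))
    boot = np.quantile(doys[idx], p / 100.0, axis=1, method="linear")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(boot, [100 * alpha, 100 * (1 - alpha)])
    return Phenometric(
        species_id="", cell_id="", year=0, source="incidental",
        percentile=int(p), doy_estimate=est,
        ci_low=float(min(lo, est)), ci_high=float(max(hi, est)),
        n_records=int(doys.size))


def incidental_phenometrics(records: pd.DataFrame, percentiles=(10, 50),
                            B: int = 500, seed: int = 0,
                            level: float = 0.95) -> pd.DataFrame:
    """Dedup, filter, and bootstrap quantile phenometrics for a whole
    occurrence table.  One row per unit x percentile; output is invariant
    to input row order."""
    df = assign_cells(deduplicate_occurrences(records))
    df["year"] = pd.to_datetime(df["date"]).dt.year
    df["doy"] = pd.to_datetime(df["date"]).dt.dayofyear
    units = filter_incidental_units(df)
    ss = np.random.SeedSequence(seed)
    rows = []
    units = units.sort_values(["species_id", "cell_id", "year"])
    for (_, u), child in zip(units.iterrows(),
                             ss.spawn(len(units)) if len(units) else []):
        sub = df[(df["species_id"] == u["species_id"])
                 & (df["cell_id"] == u["cell_id"])
                 & (df["year"] == u["year"])]
        doys = np.sort(sub["doy"].to_numpy(dtype=float))
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        for k, p in enumerate(percentiles):
            pm = bootstrap_incidental_phenometric(doys, p, B=B,
                                                  seed=sub_seed + k,
                                                  level=level)
            rows.append({
                "species_id": u["species_id"], "cell_id": u["cell_id"],
                "year": int(u["year"]), "source": "incidental",
                "percentile": pm.percentile,
                "doy_estimate": pm.doy_estimate, "ci_low": pm.ci_low,
                "ci_high": pm.ci_high, "n_records": pm.n_records,
            })
    return pd.DataFrame(rows, columns=[
        "species_id", "cell_id", "year", "source", "percentile",
        "doy_estimate", "ci_low", "ci_high", "n_records"])
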