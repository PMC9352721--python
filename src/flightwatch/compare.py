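"""Cross-stream comparison of survey and incidental phenometrics.

Pairs the two streams at the species-cell-year-percentile grain, runs the
"day 0" sanity check against field-guide-style onset references, and
summarizes confidence-interval overlap and the drivers of CI width.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

UNIT_KEYS = ["species_id", "cell_id", "year", "percentile"]


def match_paired_units(survey_pm: pd.DataFrame,
                       incidental_pm: pd.DataFrame) -> pd.DataFrame:
    """Inner join of the two phenometric tables on unit keys.

    Only units with estimates from BOTH streams are retained; unmatched
    rows are counted and logged.  Duplicate keys within one stream raise.
    Output columns: unit keys + doy/ci columns suffixed _survey and
    _incidental, per-unit delta (incidental - survey) and a ci_overlap
    flag (closed intervals: touching counts as overlap).
    """
    for name, df in (("survey", survey_pm), ("incidental", incidental_pm)):
        if df.duplicated(subset=UNIT_KEYS).any():
            dups = df[df.duplicated(subset=UNIT_KEYS, keep=False)]
            raise ValueError(f"duplicate unit keys in {name} stream: "
                             f"{dups[UNIT_KEYS].to_dict('records')[:5]}")
    if len(incidental_pm) == 0 or len(survey_pm) == 0:
        import warnings
        warnings.warn("one stream is empty; no paired units")
        return pd.DataFrame(columns=UNIT_KEYS + [
            "doy_survey", "ci_low_survey", "ci_high_survey",
            "doy_incidental", "ci_low_incidental", "ci_high_incidental",
            "delta_doy", "ci_overlap"])
    s = survey_pm.rename(columns={
        "doy_estimate": "doy_survey", "ci_low": "ci_low_survey",
        "ci_high": "ci_high_survey"})
    i = incidental_pm.rename(columns={
        "doy_estimate": "doy_incidental", "ci_low": "ci_low_incidental",
        "ci_high": "ci_high_incidental"})
    keep_s = UNIT_KEYS + ["doy_survey", "ci_low_survey", "ci_high_survey",
                          "n_surveys", "n_sites", "n_positive_surveys"]
    keep_i = UNIT_KEYS + ["doy_incidental", "ci_low_incidental",
                          "ci_high_incidental", "n_records"]
    pairs = s[[c for c in keep_s if c in s.columns]].merge(
        i[[c for c in keep_i if c in i.columns]], on=UNIT_KEYS, how="inner")
    log.info("paired %d units; dropped %d survey-only, %d incidental-only",
             len(pairs), len(s) - len(pairs), len(i) - len(pairs))
    pairs["delta_doy"] = pairs["doy_incidental"] - pairs["doy_survey"]
    pairs["ci_overlap"] = (
        (pairs["ci_low_survey"] <= pairs["ci_high_incidental"])
        & (pairs["ci_low_incidental"] <= pairs["ci_high_survey"]))
    return pairs


# ---------------------------------------------------------------------------
# day-0 sanity check


def day0_lag(phenometric_row, day0_refs: pd.DataFrame) -> float:
    """Lag (days) of one 10% estimate past its species' day-0 anchor.

    day0 = field-guide onset - 7; a negative lag flags an implausibly
    early estimate.  Missing reference -> NaN (unit skipped, logged)."""
    sp = phenometric_row["species_id"]
    ref = day0_refs[day0_refs["species_id"] == sp]
    if len(ref) == 0:
        log.info("no day-0 reference for %s; unit skipped", sp)
        return float("nan")
    day0 = float(ref["guide_onset_doy"].iloc[0]) - 7.0
    return float(phenometric_row["doy_estimate"]) - day0


def summarize_day0(phenometrics: pd.DataFrame,
                   day0_refs: pd.DataFrame) -> pd.DataFrame:
    """Per stream: fraction of 10% estimates falling before day 0."""
    p10 = phenometrics[phenometrics["percentile"] == 10].copy()
    refs = day0_refs.copy()
    refs["day0"] = refs["guide_onset_doy"] - 7
    p10 = p10.merge(refs[["species_id", "day0"]], on="species_id",
                    how="left")
    n_skipped = int(p10["day0"].isna().sum())
    if n_skipped:
        log.info("%d units without day-0 reference skipped", n_skipped)
    p10 = p10.dropna(subset=["day0"])
    p10["lag"] = p10["doy_estimate"] - p10["day0"]
    out = (p10.groupby("source")
           .agg(n_units=("lag", "size"),
                n_before_day0=("lag", lambda x: int((x < 0).sum())),
                mean_lag=("lag", "mean"))
           .reset_index())
    out["frac_before_day0"] = out["n_before_day0"] / out["n_units"]
    return out


# ---------------------------------------------------------------------------
# CI overlap and width analyses


def ci_overlap_summary(pairs: pd.DataFrame,
                       min_units_persistent: int = 3) -> dict:
    """Overlap rates overall and per species; species whose incidental
    estimates are strictly earlier than the survey estimates in every
    matched unit (with >= min_units_persistent units) are listed as
    persistently earlier."""
    if len(pairs) == 0:
        raise ValueError("no paired units")
    per_species = (pairs.groupby("species_id")
                   .agg(n_units=("ci_overlap", "size"),
                        overlap_rate=("ci_overlap", "mean"),
                        n_incidental_earlier=("delta_doy",
                                              lambda d: int((d < 0).sum())))
                   .reset_index())
    persistent = per_species[
        (per_species["n_units"] >= min_units_persistent)
        & (per_species["n_incidental_earlier"] == per_species["n_units"])
    ]["species_id"].tolist()
    return {
        "overall_overlap_rate": float(pairs["ci_overlap"].mean()),
        "per_species": per_species,
        "persistently_earlier_species": persistent,
    }


def ci_width_regression(phenometrics: pd.DataFrame,
                        traits: pd.DataFrame) -> pd.DataFrame:
    """Linear model of CI width on effort (stream-specific covariates) and
    species confusability; one fitted row set per stream x percentile."""
    pm = phenometrics.merge(traits[["species_id", "confusability"]],
                            on="species_id", how="left")
    pm = pm.dropna(subset=["ci_low", "ci_high"])
    pm["ci_width"] = pm["ci_high"] - pm["ci_low"]
    rows = []
    for (source, pct), sub in pm.groupby(["source", "percentile"]):
        effort_cols = (["n_surveys", "n_sites"] if source == "survey"
                       else ["n_records"])
        covars = effort_cols + ["confusability"]
        covars = [c for c in covars
                  if c in sub.columns and sub[c].nunique() > 1]
        if len(sub) < len(covars) + 2 or sub["ci_width"].nunique() == 1:
            import warnings
            warnings.warn(f"degenerate CI-width fit for {source} p{pct}")
            for c in covars:
                rows.append({"source": source, "percentile": pct,
                             "covariate": c, "estimate": 0.0,
                             "se": float("nan"), "p_value": float("nan"),
                             "n": len(sub)})
            continue
        fit = smf.ols("ci_width ~ " + " + ".join(covars), data=sub).fit()
        for c in covars:
            rows.append({"source": source, "percentile": pct,
                         "covariate": c,
                         "estimate": float(fit.params[c]),
                         "se": float(fit.bse[c]),
                         "p_value": float(fit.pvalues[c]),
                         "n": int(fit.nobs)})
    return pd.DataFrame(rows)
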