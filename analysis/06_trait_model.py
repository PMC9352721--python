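"""Random-intercept mixed models of the 10% phenometric on log(GDD) and
overwinter strategy, fit separately to each stream's estimates on the
shared paired units, with AIC model selection and Nakagawa-Schielzeth
pseudo-R2."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import DATA, OUT, study_config  # noqa: E402

from flightwatch import glmm, pipeline  # noqa: E402


def main():
    pairs = pd.read_csv(OUT / "paired_units.csv")
    gdd_tab = pd.read_csv(OUT / "gdd_by_cell_year.csv")
    traits = pd.read_csv(DATA / "traits.csv")
    candidates = pipeline.default_candidates(
        study_config()["model"]["candidates"])
    pct = study_config()["model"]["percentile"]
    for source in ("survey", "incidental"):
        frame = glmm.build_model_frame(pairs, gdd_tab, traits, pct, source)
        best, aic_tab = glmm.select_by_aic(frame, candidates)
        aic_tab.to_csv(OUT / f"aic_table_{source}.csv", index=False)
        glmm.coefficients_table(best).to_csv(
            OUT / f"coefficients_{source}.csv", index=False)
        print(f"\n=== {source} stream, {pct}% DOY, n={best.n_obs} units, "
              f"{best.n_species} species ===")
        print(aic_tab[["name", "n_params", "aic", "delta_aic"]]
              .round(1).to_string(index=False))
        print(glmm.coefficients_table(best).round(3).to_string(index=False))


if __name__ == "__main__":
    main()
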