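"""Compare the two streams: pair phenometrics per species-cell-year, run
the day-0 sanity check, and summarize CI overlap and the effort drivers
of CI width."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import DATA, OUT  # noqa: E402

from flightwatch import compare  # noqa: E402


def main():
    pm_s = pd.read_csv(OUT / "phenometrics_survey.csv")
    pm_i = pd.read_csv(OUT / "phenometrics_incidental.csv")
    pairs = compare.match_paired_units(pm_s, pm_i)
    pairs.to_csv(OUT / "paired_units.csv", index=False)
    print(f"{len(pairs)} paired unit-percentiles "
          f"(from {len(pm_s)} survey + {len(pm_i)} incidental rows)")

    refs = pd.read_csv(DATA / "day0_refs.csv")
    all_pm = pd.concat([pm_s, pm_i], ignore_index=True)
    day0 = compare.summarize_day0(all_pm, refs)
    day0.to_csv(OUT / "day0_summary.csv", index=False)
    print("\nday-0 check (fraction of 10% estimates before day 0):")
    print(day0.round(3).to_string(index=False))

    overlap = compare.ci_overlap_summary(pairs)
    overlap["per_species"].to_csv(OUT / "ci_overlap_species.csv",
                                  index=False)
    print(f"\noverall 95% CI overlap: "
          f"{overlap['overall_overlap_rate']:.1%}; persistently earlier "
          f"incidental: {overlap['persistently_earlier_species'] or 'none'}")

    traits = pd.read_csv(DATA / "traits.csv")
    widths = compare.ci_width_regression(all_pm, traits)
    widths.to_csv(OUT / "ci_width_effects.csv", index=False)
    print("\nCI-width effort effects (estimate per covariate):")
    print(widths.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
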