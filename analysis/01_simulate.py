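"""Generate the synthetic study region: climate, species pool, true
flight curves, transect surveys, and incidental occurrence records.

Writes climate/traits/truth/gdd/surveys/occurrences/day0_refs CSVs under
results/data/ and prints the basic data-density numbers.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import DATA, SEED, study_config  # noqa: E402

from flightwatch import pipeline  # noqa: E402


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    art = pipeline._simulate(study_config(), SEED, DATA)
    surveys, occ = art["surveys"], art["occurrences"]
    print(f"climate days: {len(art['climate'])} across "
          f"{art['climate']['cell_id'].nunique()} cells")
    print(f"species: {len(art['traits'])}; "
          f"true units: {len(art['truth'])}")
    print(f"surveys: {len(surveys)} rows, "
          f"{(surveys['count'] > 0).mean():.1%} with detections")
    print(f"incidental records: {len(occ)} "
          f"({occ['platform'].value_counts().to_dict()})")


if __name__ == "__main__":
    main()
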