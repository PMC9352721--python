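"""Shared paths and the study configuration for the analysis scripts.

One place to change scale: 6 species, 4 one-degree cells, 3 years —
enough units for every downstream table while keeping a full re-run of
01-06 under a few minutes on one core.
"""

from pathlib import Path

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def study_config() -> dict:
    from flightwatch import pipeline

    cfg = pipeline.demo_config()
    cfg["simulate"]["n_species"] = 6
    cfg["phenometrics"]["bootstrap_survey"] = 100
    return cfg
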