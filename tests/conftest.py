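import numpy as np
import pandas as pd
import pytest

from flightwatch import synth
from flightwatch.types import SpeciesTraits, SurveyDesign, TruePhenology


def gaussian_truth(mu=180.0, sd=10.0, total=400.0, species="sp000",
                   cell="38_-89", year=2016) -> TruePhenology:
    """Univoltine Gaussian flight-curve truth with analytic quantiles."""
    z10 = 1.2815515655446004
    return TruePhenology(species, cell, year, [mu], [sd], [1.0],
                         true_doy10=mu - z10 * sd, true_doy50=mu,
                         seasonal_total=total)


def one_species_traits(detectability=0.8, voltinism=1,
                       overwinter="pupa") -> SpeciesTraits:
    return SpeciesTraits("sp000", overwinter, voltinism, "generalist", 1,
                         40.0, 3, 0, 0, detectability, 0.1)


@pytest.fixture
def unit_surveys() -> pd.DataFrame:
    """One well-sampled species-cell-year of transect counts,
    Gaussian(180, 10) truth."""
    truth = [gaussian_truth()]
    design = SurveyDesign(n_sites_per_cell=5, season_start_doy=100,
                          season_end_doy=273, visit_interval_days=7)
    return synth.simulate_surveys(truth, design, [one_species_traits()],
                                  seed=3)


@pytest.fixture
def species_pool():
    return synth.generate_species_pool(10, synth.CoefTruth(), seed=11)


def toy_survey_table(n_sites=3, n_visits=5, counts=None,
                     cell="38_-89", year=2016, species="spA"):
    """Compact survey table builder for filter-contract tests.

    ``counts[i][j]`` is the count at site i, visit j; visits are weekly
    from DOY 150.
    """
    rows = []
    for i in range(n_sites):
        for j in range(n_visits):
            date = (pd.Timestamp(f"{year}-01-01")
                    + pd.Timedelta(days=149 + 7 * j))
            c = counts[i][j] if counts is not None else 0
            rows.append({"site_id": f"s{i}", "date": date.date().isoformat(),
                         "species_id": species, "count": c,
                         "cell_id": cell})
    return pd.DataFrame(rows)
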