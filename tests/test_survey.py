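"""Survey-stream flight curves: eligibility filters, penalized-spline
fits, percentile extraction, and the visit bootstrap."""

import numpy as np
import pandas as pd
import pytest

from flightwatch import survey, synth
from flightwatch.types import FlightCurve, SurveyDesign

from conftest import gaussian_truth, one_species_traits, toy_survey_table


def _eligible(df):
    out = survey.filter_survey_units(df)
    return set(map(tuple, out[["species_id", "cell_id", "year"]].values))


class TestFilters:
    def _counts(self, n_sites, n_visits, detect_pattern):
        """detect_pattern[i][j] = 1 puts one individual at site i visit j."""
        return [[detect_pattern[i][j] for j in range(n_visits)]
                for i in range(n_sites)]

    def test_survey_count_threshold(self):
        # 3 sites x 3 visits = 9 surveys -> rejected; 10 surveys eligible
        pat = [[0, 1, 1], [0, 1, 1], [0, 1, 1]]
        nine = toy_survey_table(3, 3, pat)
        assert _eligible(nine) == set()
        pat4 = [[0, 1, 1, 1], [0, 1, 1, 1], [0, 1, 1, 0]]
        ten_plus = toy_survey_table(3, 4, pat4)  # 12 surveys, 3 sites
        assert _eligible(ten_plus) == {("spA", "38_-89", 2016)}

    def test_site_threshold(self):
        pat = [[0, 1, 1, 1, 1, 1], [0, 1, 1, 1, 1, 1]]
        twelve_two_sites = toy_survey_table(2, 6, pat)
        assert _eligible(twelve_two_sites) == set()

    def test_four_detection_rule(self):
        pat3 = [[0, 1, 1, 0], [0, 1, 0, 0], [0, 0, 0, 0]]  # 3 detections
        assert _eligible(toy_survey_table(3, 4, pat3)) == set()
        pat4 = [[0, 1, 1, 1], [0, 1, 0, 0], [0, 0, 0, 0]]  # 4 detections
        assert _eligible(toy_survey_table(3, 4, pat4)) == {
            ("spA", "38_-89", 2016)}

    def test_first_survey_rule(self):
        # detected in every occupied site's first visit -> rejected
        pat = [[1, 1, 1, 1], [1, 1, 0, 0], [0, 0, 0, 0]]
        assert _eligible(toy_survey_table(3, 4, pat)) == set()
        # one occupied site starts with an absence -> eligible
        pat_ok = [[1, 1, 1, 1], [0, 1, 0, 0], [0, 0, 0, 0]]
        assert _eligible(toy_survey_table(3, 4, pat_ok)) == {
            ("spA", "38_-89", 2016)}

    def test_requires_absence_rows(self):
        pat = [[1, 1, 1, 1], [1, 1, 1, 1], [1, 1, 1, 1]]
        with pytest.raises(ValueError, match="absence"):
            survey.filter_survey_units(toy_survey_table(3, 4, pat))


class TestFit:
    def test_curve_is_normalized_cdf_valid(self, unit_surveys):
        c = survey.fit_flight_curve(unit_surveys)
        assert np.trapezoid(c.density, c.doy_grid) == pytest.approx(
            1.0, abs=1e-9)
        assert c.cumulative[0] == pytest.approx(0.0, abs=1e-12)
        assert c.cumulative[-1] == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(c.cumulative) >= -1e-12).all()

    def test_single_doy_detections_concentrate(self):
        pat = [[0, 0, 9, 0, 0], [0, 0, 5, 0, 0], [0, 0, 2, 0, 0]]
        df = toy_survey_table(3, 5, pat)
        d = 150 + 7 * 2 + 1  # DOY of the third visit (2016 is a leap year)
        doy = pd.to_datetime(df["date"]).dt.dayofyear
        d = int(doy[(df["count"] > 0)].iloc[0])
        c = survey.fit_flight_curve(df)
        assert survey.percentile_from_curve(c, 10) == pytest.approx(d, abs=1)
        assert survey.percentile_from_curve(c, 50) == pytest.approx(d, abs=1)

    def test_site_effect_absorbs_abundance_scaling(self):
        """Two sites with exactly proportional (noiseless) counts: scaling
        one site's abundance is absorbed by its site effect, and the
        normalized curve barely moves (exact only in the interpolation
        limit, so a light penalty and a tight-but-finite tolerance)."""
        doys = np.arange(130, 231, 5)
        dens = np.exp(-0.5 * ((doys - 180.0) / 12.0) ** 2)
        rows = []
        for site, mult in (("a", 1.0), ("b", 3.0)):
            for d, c in zip(doys, 40.0 * mult * dens):
                date = (pd.Timestamp("2016-01-01")
                        + pd.Timedelta(days=int(d) - 1))
                rows.append({"site_id": site,
                             "date": date.date().isoformat(),
                             "species_id": "spA", "count": c,
                             "cell_id": "38_-89"})
        df = pd.DataFrame(rows)
        cfg = survey.SplineConfig(fixed_lambda=1e-3)
        base = survey.fit_flight_curve(df, cfg)
        scaled = df.copy()
        scaled.loc[scaled["site_id"] == "a", "count"] *= 5
        alt = survey.fit_flight_curve(scaled, cfg)
        assert np.allclose(base.density, alt.density, atol=1e-4)
        for p in (10, 50):
            assert survey.percentile_from_curve(alt, p) == pytest.approx(
                survey.percentile_from_curve(base, p), abs=0.05)

    def test_dense_noiseless_recovery(self):
        """Expected (real-valued) counts from a Gaussian(180, 10) truth:
        the fitted 50% DOY lands within 2 days of 180."""
        doys = np.arange(120, 241)
        rows = []
        for site, mult in (("a", 1.0), ("b", 2.5)):
            dens = np.exp(-0.5 * ((doys - 180.0) / 10.0) ** 2)
            for d, c in zip(doys, 500.0 * mult * dens / (10 * np.sqrt(2 * np.pi))):
                date = pd.Timestamp("2016-01-01") + pd.Timedelta(days=int(d) - 1)
                rows.append({"site_id": site, "date": date.date().isoformat(),
                             "species_id": "spA", "count": c,
                             "cell_id": "38_-89"})
        df = pd.DataFrame(rows)
        c = survey.fit_flight_curve(df)
        assert survey.percentile_from_curve(c, 50) == pytest.approx(
            180.0, abs=2.0)
        assert survey.percentile_from_curve(c, 10) == pytest.approx(
            167.2, abs=2.0)

    def test_all_zero_counts_error(self, unit_surveys):
        z = unit_surveys.copy()
        z["count"] = 0
        with pytest.raises(survey.FitError):
            survey.fit_flight_curve(z)


def _uniform_curve():
    grid = np.arange(100, 200)
    dens = np.full(grid.size, 1.0)
    dens /= np.trapezoid(dens, grid)
    cum = np.concatenate([[0.0], np.cumsum(
        (dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
    cum /= cum[-1]
    return FlightCurve("s", "c", 2016, grid, dens, cum)


class TestPercentileExtraction:
    def test_uniform_inversion(self):
        c = _uniform_curve()
        assert survey.percentile_from_curve(c, 50) == pytest.approx(
            149.5, abs=0.01)
        assert survey.percentile_from_curve(c, 10) == pytest.approx(
            109.9, abs=0.01)

    def test_monotone_in_p(self, unit_surveys):
        c = survey.fit_flight_curve(unit_surveys)
        ps = [5, 10, 25, 50, 75, 90]
        vals = [survey.percentile_from_curve(c, p) for p in ps]
        assert vals == sorted(vals)

    def test_matches_bruteforce_cdf_inversion(self, unit_surveys):
        c = survey.fit_flight_curve(unit_surveys)
        for p in (10, 50):
            q = p / 100
            # brute force: first grid day whose trapezoid CDF reaches q
            brute = c.doy_grid[np.searchsorted(c.cumulative, q)]
            assert abs(survey.percentile_from_curve(c, p) - brute) <= 1.0


class TestBootstrap:
    def test_degenerate_single_doy_zero_width(self):
        pat = [[0, 0, 9, 0, 0], [0, 0, 5, 0, 0], [0, 0, 2, 0, 0]]
        df = toy_survey_table(3, 5, pat)
        pm = survey.bootstrap_survey_phenometric(df, 50, B=50, seed=0)
        assert pm.ci_width == pytest.approx(0.0, abs=1e-9)

    def test_effort_metadata_and_ci_order(self, unit_surveys):
        pm = survey.bootstrap_survey_phenometric(unit_surveys, 50, B=50,
                                                 seed=1)
        assert pm.ci_low <= pm.doy_estimate <= pm.ci_high
        assert pm.n_sites == 5
        assert pm.n_surveys == len(unit_surveys)
        assert pm.n_positive_surveys == (unit_surveys["count"] > 0).sum()

    def test_more_surveys_tighter_intervals(self):
        """Median CI width shrinks when the visit density doubles."""
        traits = [one_species_traits()]
        widths = {}
        for interval in (14, 7):
            w = []
            for i in range(8):
                truth = [gaussian_truth(mu=175.0 + i)]
                design = SurveyDesign(n_sites_per_cell=4,
                                      season_start_doy=100,
                                      season_end_doy=273,
                                      visit_interval_days=interval)
                sv = synth.simulate_surveys(truth, design, traits,
                                            seed=100 + i)
                pm = survey.bootstrap_survey_phenometric(sv, 50, B=100,
                                                         seed=i)
                w.append(pm.ci_width)
            widths[interval] = np.median(w)
        assert widths[7] < widths[14]


def test_survey_phenometrics_table(unit_surveys):
    """End-to-end table for one cell-year: both percentiles, ordered."""
    pm = survey.survey_phenometrics(unit_surveys, B=50, seed=0)
    assert set(pm["percentile"]) == {10, 50}
    wide = pm.pivot(index=["species_id", "cell_id", "year"],
                    columns="percentile", values="doy_estimate")
    assert (wide[10] <= wide[50]).all()
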