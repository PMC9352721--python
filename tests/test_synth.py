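"""Synthetic-data generator: determinism, closed-form truths, and the
statistical structure of both observation processes."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flightwatch import synth
from flightwatch.types import SurveyDesign

from conftest import gaussian_truth, one_species_traits

CELLS = [(38, -89), (39, -88)]


class TestClimate:
    def test_constant_forcing(self):
        p = synth.ClimateParams(annual_mean=20.0, amplitude=0.0,
                                diurnal_range=10.0, noise_sd=0.0,
                                lat_gradient=0.0)
        clim = synth.generate_climate(CELLS, [2015], p, seed=1)
        assert (clim["tmin"] == 15.0).all()
        assert (clim["tmax"] == 25.0).all()
        assert len(clim) == 2 * 365

    def test_determinism(self):
        p = synth.ClimateParams()
        a = synth.generate_climate(CELLS, [2015, 2016], p, seed=1)
        b = synth.generate_climate(CELLS, [2015, 2016], p, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_sinusoid_peaks_on_peak_day(self):
        p = synth.ClimateParams(annual_mean=10.0, amplitude=15.0,
                                peak_doy=200.0, noise_sd=0.0,
                                lat_gradient=0.0)
        clim = synth.generate_climate([CELLS[0]], [2015], p, seed=1)
        doy = pd.to_datetime(clim["date"]).dt.dayofyear
        assert doy[clim["tmax"].idxmax()] == 200

    def test_tmin_never_exceeds_tmax(self):
        clim = synth.generate_climate(CELLS, [2015],
                                      synth.ClimateParams(noise_sd=4.0),
                                      seed=2)
        assert (clim["tmin"] <= clim["tmax"]).all()

    def test_rejects_nonpositive_diurnal_range(self):
        with pytest.raises(ValueError):
            synth.ClimateParams(diurnal_range=0.0)


class TestSpeciesPool:
    def test_all_classes_present_at_five(self):
        traits, _ = synth.generate_species_pool(5, synth.CoefTruth(), seed=0)
        assert {t.overwinter_class for t in traits} == set(
            ("egg", "larva", "pupa", "adult", "migrant"))

    def test_forty_unique_ids(self):
        traits, _ = synth.generate_species_pool(40, synth.CoefTruth(),
                                                seed=0)
        assert len({t.species_id for t in traits}) == 40

    def test_zero_random_intercept_sd_degenerate(self):
        _, coef = synth.generate_species_pool(
            8, synth.CoefTruth(sigma_species=0.0), seed=0)
        assert (coef["alpha_species"] == 0.0).all()

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            synth.CoefTruth(sigma_species=-1.0)


def _gdd_tab(gdds, year=2016):
    return pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(gdds))],
                         "year": year, "gdd": gdds})


class TestTruePhenology:
    def test_gdd_doubling_shifts_by_slope_ln2(self):
        ct = synth.CoefTruth(slope_log_gdd=-30.0, sigma_species=0.0,
                             sigma_unit=0.0)
        pool = synth.generate_species_pool(1, ct, seed=0)
        truth = synth.simulate_true_phenology(pool, _gdd_tab([600.0, 1200.0]),
                                              ct, seed=0)
        shift = (truth[0].generation_means[0] - truth[1].generation_means[0])
        assert shift == pytest.approx(30.0 * np.log(2.0), abs=1e-9)

    def test_univoltine_quantiles_match_normal_oracle(self):
        t = gaussian_truth(mu=180.0, sd=10.0)
        assert t.true_doy10 == pytest.approx(180 - 1.2815515655 * 10,
                                             abs=1e-6)
        assert t.true_doy50 == pytest.approx(180.0, abs=1e-6)
        # numeric inversion agrees with the analytic normal quantile
        assert synth.mixture_quantile(0.10, [180.0], [10.0], [1.0]) == \
            pytest.approx(t.true_doy10, abs=0.01)

    def test_bimodal_median_falls_in_gap(self):
        q50 = synth.mixture_quantile(0.50, [150.0, 230.0], [5.0, 5.0],
                                     [0.5, 0.5])
        assert 150 + 15 <= q50 <= 230 - 15

    def test_doy10_leq_doy50_and_generation_count(self, species_pool):
        traits, coef = species_pool
        ct = synth.CoefTruth()
        truth = synth.simulate_true_phenology((traits, coef),
                                              _gdd_tab([700.0, 1100.0]),
                                              ct, seed=1)
        volt = {t.species_id: t.voltinism for t in traits}
        for u in truth:
            assert u.true_doy10 <= u.true_doy50
            assert len(u.generation_means) == volt[u.species_id]

    def test_invalid_gdd_skips_with_warning(self, species_pool):
        tab = _gdd_tab([800.0, -5.0])
        with pytest.warns(UserWarning, match="skipped"):
            truth = synth.simulate_true_phenology(
                species_pool, tab, synth.CoefTruth(), seed=1)
        assert {u.cell_id for u in truth} == {"c0"}


class TestSurveyProcess:
    def test_absences_recorded_at_low_detectability(self):
        tr = one_species_traits(detectability=1e-9)
        sv = synth.simulate_surveys([gaussian_truth()], SurveyDesign(),
                                    [tr], seed=0)
        assert len(sv) > 0
        assert (sv["count"] == 0).all()

    def test_site_multiplier_ratio(self):
        design = SurveyDesign(n_sites_per_cell=2, season_start_doy=100,
                              season_end_doy=260, visit_interval_days=2,
                              site_abundance_multipliers=[3.0, 1.0])
        truth = [gaussian_truth(total=50_000.0)]
        sv = synth.simulate_surveys(truth, design, [one_species_traits()],
                                    seed=1)
        tot = sv.groupby("site_id")["count"].sum()
        ratio = tot.iloc[0] / tot.iloc[1]
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_no_survey_before_season_start(self):
        design = SurveyDesign(season_start_doy=152, season_end_doy=273)
        truth = [gaussian_truth(mu=150.0)]  # true_doy10 ~ 137, pre-season
        sv = synth.simulate_surveys(truth, design, [one_species_traits()],
                                    seed=1)
        doys = pd.to_datetime(sv["date"]).dt.dayofyear
        assert doys.min() >= 152

    def test_determinism(self, unit_surveys):
        truth = [gaussian_truth()]
        design = SurveyDesign(n_sites_per_cell=5, season_start_doy=100,
                              season_end_doy=273, visit_interval_days=7)
        again = synth.simulate_surveys(truth, design,
                                       [one_species_traits()], seed=3)
        pd.testing.assert_frame_equal(unit_surveys, again)


class TestIncidentalProcess:
    def test_presence_only_with_coordinates_in_cell(self):
        occ = synth.simulate_incidental([gaussian_truth(total=1.0)],
                                        synth.EffortModel.flat(200.0),
                                        [one_species_traits()], seed=0)
        assert "count" not in occ.columns
        assert len(occ) > 0
        assert ((occ["lat"] >= 38) & (occ["lat"] < 39)).all()
        assert ((occ["lon"] >= -89) & (occ["lon"] < -88)).all()

    def test_flat_effort_matches_curve_shape_ks(self):
        occ = synth.simulate_incidental([gaussian_truth()],
                                        synth.EffortModel.flat(2500.0),
                                        [one_species_traits(1.0)], seed=4)
        doys = pd.to_datetime(occ["date"]).dt.dayofyear.to_numpy()
        assert len(doys) >= 2000
        p = stats.kstest(doys, stats.norm(180.0, 10.0).cdf).pvalue
        assert p > 0.01  # day-rounding only; shape follows the curve

    def test_zero_effort_censors_hard(self):
        eff = synth.EffortModel(ramp=[(1, 0.0), (149, 0.0), (150, 1.0),
                                      (365, 1.0)], weekend_multiplier=1.0,
                                base_rate=400.0)
        occ = synth.simulate_incidental([gaussian_truth(mu=155.0)], eff,
                                        [one_species_traits()], seed=0)
        doys = pd.to_datetime(occ["date"]).dt.dayofyear
        assert doys.min() >= 150

    def test_expected_count_linear_in_effort(self):
        t = one_species_traits(1.0)
        ns = []
        for mult in (1.0, 3.0):
            occ = synth.simulate_incidental(
                [gaussian_truth()], synth.EffortModel.flat(800.0 * mult),
                [t], seed=9)
            ns.append(len(occ))
        assert ns[1] / ns[0] == pytest.approx(3.0, rel=0.1)

    def test_all_zero_effort_warns_empty(self):
        eff = synth.EffortModel(ramp=[(1, 0.0), (365, 0.0)],
                                weekend_multiplier=1.0)
        with pytest.warns(UserWarning, match="effort"):
            occ = synth.simulate_incidental([gaussian_truth()], eff,
                                            [one_species_traits()], seed=0)
        assert len(occ) == 0

    def test_empirical_quantiles_converge_to_truth(self):
        """Flat effort, detectability 1: sample quantiles at n~10,000 land
        within a day of the analytic mixture quantiles."""
        t = gaussian_truth(mu=180.0, sd=10.0)
        occ = synth.simulate_incidental([t], synth.EffortModel.flat(10_000.0),
                                        [one_species_traits(1.0)], seed=2)
        doys = pd.to_datetime(occ["date"]).dt.dayofyear.to_numpy(dtype=float)
        assert len(doys) >= 9000
        assert np.quantile(doys, 0.10) == pytest.approx(t.true_doy10, abs=1.0)
        assert np.quantile(doys, 0.50) == pytest.approx(t.true_doy50, abs=1.0)


def test_model_frame_simulator_recovers_structure():
    ct = synth.CoefTruth(sigma_species=0.0, sigma_unit=0.0)
    fr = synth.simulate_model_frame(100, 10, ct, seed=0)
    # exact linear structure when both noise sources are off
    resid = (fr["doy"]
             - fr["overwinter_class"].map(ct.stage_intercepts)
             - ct.slope_log_gdd * fr["log_gdd"])
    assert np.allclose(resid, 0.0, atol=1e-9)
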