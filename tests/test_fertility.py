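"""Two-stage ASFR estimation, aggregate splitting, extreme ages, SRB."""

import numpy as np
import pytest

from popfert import fertility as fert
from popfert import synthetic
from popfert.fertility import (ASFREstimate, ExtremeAgeModel,
                               FertilityObservation, apply_extreme_ages,
                               cohort_ceb_from_single, estimate_srb,
                               fit_extreme_age_model, fit_final,
                               fit_stage1, resolve_reference,
                               split_aggregates)


@pytest.fixture(scope="module")
def fert_truth():
    sc = synthetic.CountryScenario(year_start=1950, year_end=2000,
                                   tfr_start=6.5, tfr_end=2.5)
    return synthetic.make_true_country(sc, seed=11)


def _group_truth(truth):
    return truth.true_asfr.reshape(-1, 9, 5).mean(axis=2)   # (T, 9)


class TestStage1:
    def test_dense_exact_vr_is_interpolated(self, fert_truth):
        data = synthetic.observe_fertility_sources(
            fert_truth, synthetic.ObservationConfig(vr_noise_sd=0.0))
        est = fit_stage1(data, fert_truth.years[:-1])
        rel = np.abs(est.asfr[1:8] / _group_truth(fert_truth).T[1:8] - 1.0)
        assert rel.max() < 0.005

    def test_biased_secondary_source_recovery(self, fert_truth):
        cfg = synthetic.ObservationConfig(
            vr_bias={"vr": 1.0, "registry_b": 0.8}, vr_noise_sd=0.02)
        data = synthetic.observe_fertility_sources(fert_truth, cfg)
        for o in data:
            if o.source_id == "vr":
                o.reference = True
        est = fit_stage1(data, fert_truth.years[:-1])
        rel = np.abs(est.asfr[1:8] / _group_truth(fert_truth).T[1:8] - 1.0)
        assert rel.max() < 0.05

    def test_draw_means_match_point_estimate(self, fert_truth):
        data = synthetic.observe_fertility_sources(
            fert_truth, synthetic.ObservationConfig(vr_noise_sd=0.02))
        est = fit_stage1(data, fert_truth.years[:-1])
        assert est.draws is not None
        m = est.draws.mean(axis=0)
        pos = est.asfr > 0
        assert np.max(np.abs(m[pos] / est.asfr[pos] - 1.0)) < 1e-6

    def test_no_reference_source_error_lists_candidates(self):
        obs = [FertilityObservation("x", 1990, "sbh", "s1", 20, "ceb", 2.0)]
        with pytest.raises(ValueError, match="candidates"):
            resolve_reference(obs)

    def test_reference_cascade_prefers_vr_then_dhs(self):
        mk = lambda st_, sid: FertilityObservation(
            "x", 1990, st_, sid, 20, "asfr", 0.1)
        assert resolve_reference([mk("cbh", "cbh_dhs_1990"),
                                  mk("vr", "vr_a")]) == "vr_a"
        assert resolve_reference([mk("cbh", "survey_z"),
                                  mk("cbh", "cbh_dhs_1990")]) \
            == "cbh_dhs_1990"


@pytest.fixture(scope="module")
def stage1(fert_truth):
    data = synthetic.observe_fertility_sources(
        fert_truth, synthetic.ObservationConfig(vr_noise_sd=0.0))
    return fit_stage1(data, fert_truth.years[:-1])


class TestSplitAggregates:
    def _sbh_from_surface(self, surface, years, survey, cohorts):
        return [FertilityObservation(
            "x", survey, "sbh", f"s{survey}", c, "ceb",
            cohort_ceb_from_single(surface, years, c, survey),
            variance=1e-4) for c in cohorts]

    def test_consistent_ceb_gives_ratio_one(self, stage1):
        years = stage1.years
        obs = self._sbh_from_surface(stage1.single_age(), years, 1985,
                                     range(20, 50, 5))
        pseudo = split_aggregates(obs, stage1)
        for p in pseudo:
            base = stage1.group_row(p.age_start)[p.year - years[0]]
            assert p.value == pytest.approx(base, rel=1e-12)

    def test_linear_in_observed_ceb(self, stage1):
        years = stage1.years
        obs = self._sbh_from_surface(stage1.single_age(), years, 1985,
                                     [30])
        doubled = [FertilityObservation(
            o.location, o.year, o.source_type, o.source_id, o.age_start,
            o.measure, 2 * o.value, o.variance) for o in obs]
        p1 = split_aggregates(obs, stage1)
        p2 = split_aggregates(doubled, stage1)
        for a, b in zip(p1, p2):
            assert b.value == pytest.approx(2 * a.value, rel=1e-12)

    def test_constant_bias_recovered_exactly(self, stage1):
        # truth differing from stage 1 by factor k: pseudo-points land on
        # k * stage1 = truth
        k = 1.37
        years = stage1.years
        obs = self._sbh_from_surface(k * stage1.single_age(), years, 1990,
                                     range(20, 50, 5))
        pseudo = split_aggregates(obs, stage1)
        assert pseudo
        for p in pseudo:
            target = k * stage1.group_row(p.age_start)[p.year - years[0]]
            assert p.value == pytest.approx(target, rel=1e-12)

    def test_zero_implied_with_positive_ceb_errors(self, stage1):
        bad = [FertilityObservation("x", int(stage1.years[0]), "sbh", "s",
                                    15, "ceb", 1.0, 1e-4)]
        with pytest.raises(ValueError, match="implied"):
            split_aggregates(bad, stage1)


class TestFinal:
    def test_no_aggregates_is_fixed_point(self, fert_truth):
        data = synthetic.observe_fertility_sources(
            fert_truth, synthetic.ObservationConfig(vr_noise_sd=0.01))
        st1 = fit_stage1(data, fert_truth.years[:-1])
        fin = fit_final(data, fert_truth.years[:-1])
        np.testing.assert_allclose(fin.asfr, st1.asfr, rtol=1e-12)
        assert fin.stage == "final"

    def test_sbh_improves_data_sparse_past(self, fert_truth):
        cfg = synthetic.ObservationConfig(
            vr_years=tuple(range(1978, 2000)), vr_noise_sd=0.02,
            sbh_surveys=(1975, 1985), sbh_noise_sd=0.03)
        data = synthetic.observe_fertility_sources(fert_truth, cfg)
        st1 = fit_stage1(data, fert_truth.years[:-1])
        fin = fit_final(data, fert_truth.years[:-1])
        truth = _group_truth(fert_truth).T
        pre = slice(0, 25)          # years before 1975
        rmse1 = np.sqrt(np.mean((st1.asfr[1:8, pre]
                                 - truth[1:8, pre]) ** 2))
        rmse2 = np.sqrt(np.mean((fin.asfr[1:8, pre]
                                 - truth[1:8, pre]) ** 2))
        assert rmse2 < rmse1


class TestExtremeAges:
    def test_fixed_coefficients_applied(self):
        years = np.arange(1990, 1995)
        asfr = np.zeros((9, years.size))
        asfr[1] = 0.05            # 15-19
        asfr[7] = 0.004           # 45-49
        est = ASFREstimate(years=years, asfr=asfr)
        model = ExtremeAgeModel(intercept=np.log(0.01), slope=0.0,
                                r5054=0.02)
        out = apply_extreme_ages(est, model)
        np.testing.assert_allclose(out.asfr[0], 0.01 * 0.05, rtol=1e-12)
        np.testing.assert_allclose(out.asfr[8], 0.02 * 0.004, rtol=1e-12)

    def test_zero_4549_gives_zero_5054(self):
        years = np.arange(1990, 1993)
        asfr = np.zeros((9, years.size))
        asfr[1] = 0.05
        out = apply_extreme_ages(
            ASFREstimate(years=years, asfr=asfr),
            ExtremeAgeModel(intercept=-4.0, slope=1.0, r5054=0.02))
        assert np.all(out.asfr[8] == 0.0)

    def test_generate_and_refit_within_three_percent(self, fert_truth):
        rng = np.random.default_rng(8)
        truth_b0, truth_b1, truth_r = np.log(0.012), -2.0, 0.018
        gt = _group_truth(fert_truth)
        vr = []
        for t, yr in enumerate(range(1960, 2000)):
            a1519 = float(gt[yr - 1950, 1])
            a4549 = float(gt[yr - 1950, 7])
            ratio = np.exp(truth_b0 + truth_b1 * a1519)
            for g, v in ((10, a1519 * ratio
                          * np.exp(rng.normal(0, 0.01))),
                         (15, a1519), (45, a4549),
                         (50, truth_r * a4549
                          * np.exp(rng.normal(0, 0.01)))):
                vr.append(FertilityObservation("x", yr, "vr", "vr", g,
                                               "asfr", v))
        model = fit_extreme_age_model(vr)
        # predictions (not raw coefficients: the regressor range is
        # narrow) must track the generating law within 3%
        for a1519 in np.linspace(gt[:, 1].min(), gt[:, 1].max(), 7):
            pred = a1519 * np.exp(model.intercept + model.slope * a1519)
            target = a1519 * np.exp(truth_b0 + truth_b1 * a1519)
            assert pred == pytest.approx(target, rel=0.03)
        assert model.r5054 == pytest.approx(truth_r, rel=0.03)


class TestSRB:
    def test_no_data_returns_prior(self):
        years = np.arange(1950, 1960)
        s = estimate_srb([], [], [], years)
        np.testing.assert_allclose(s.srb, 0.512 / 0.488, rtol=1e-12)

    def test_constant_data_at_prior_mean(self):
        years = np.arange(1950, 1970)
        obs_y = years[::2]
        s = estimate_srb(obs_y, np.full(obs_y.size, 0.512), 1e-6, years)
        assert np.allclose(s.srb, 1.049, atol=0.002)

    def test_late_ramp_recovers_high_srb(self):
        years = np.arange(1950, 2000)
        obs_y = np.arange(1980, 2000)
        p = 0.512 + (0.539 - 0.512) * np.linspace(0, 1, obs_y.size)
        s = estimate_srb(obs_y, p, 1e-6, years)
        assert abs(s.srb[-1] - 1.17) < 0.01

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ValueError):
            estimate_srb([1990], [1.2], [1e-6], np.arange(1980, 2000))
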