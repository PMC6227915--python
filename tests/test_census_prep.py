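"""Census adjustment, quality scores, and heaping corrections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popfert import census_prep as cp
from popfert import synthetic
from popfert.census_prep import (CensusObservation, PESRecord,
                                 adjust_census, age_sex_joint_score,
                                 correct_heaping, fit_completeness_model,
                                 select_correction, whipple_index)
from popfert.synthetic import ObservationConfig, observe_census, observe_pes


def _five_year_census(counts_f, counts_m, year=1980.0):
    n = counts_f.size
    starts = np.arange(n) * 5
    ends = np.append(starts[1:], -1)
    return CensusObservation(location="x", year=year, age_start=starts,
                             age_end=ends,
                             counts=np.stack([counts_f, counts_m]))


class TestCompletenessModel:
    def test_perfect_pes_gives_unit_predictions(self):
        pes = [PESRecord("a", 1980, 1.0, s) for s in (0.2, 0.5, 0.8)]
        model = fit_completeness_model(pes)
        assert np.allclose(model.predict([0.1, 0.5, 0.9]), 1.0, atol=1e-9)
        assert np.allclose(model.age_multipliers, 1.0)

    def test_recovers_known_logistic_curve(self):
        from scipy.special import expit
        rng = np.random.default_rng(5)
        b0, b1 = 0.5, 2.0          # keeps completeness inside (0.5, 1.2)
        sdi = rng.uniform(0.1, 0.9, 80)
        comp = 1.25 * expit(b0 + b1 * sdi) \
            * np.exp(rng.normal(0, 0.01, sdi.size))
        pes = [PESRecord("a", 1980, float(c), float(s))
               for c, s in zip(comp, sdi)]
        model = fit_completeness_model(pes)
        se = np.sqrt(np.diag(model.vcov))
        assert abs(model.coef[0] - b0) < 2 * se[0]
        assert abs(model.coef[1] - b1) < 2 * se[1]

    def test_monotone_in_sdi_when_slope_positive(self):
        pes = [PESRecord("a", 1980, c, s)
               for c, s in [(0.85, 0.2), (0.92, 0.5), (0.98, 0.8)]]
        model = fit_completeness_model(pes)
        assert model.coef[1] >= 0
        pred = model.predict(np.linspace(0, 1, 11))
        assert np.all(np.diff(pred) >= -1e-12)

    def test_identical_sdi_rejected(self):
        pes = [PESRecord("a", 1980, 0.9, 0.5) for _ in range(4)]
        with pytest.raises(ValueError, match="SDI"):
            fit_completeness_model(pes)

    def test_age_pattern_mean_one(self, small_truth):
        pes = observe_pes(small_truth, range(1955, 1990, 5),
                          ObservationConfig(seed=4), noise_sd=0.005)
        model = fit_completeness_model(pes)
        assert model.age_multipliers.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(model.age_multipliers > 0)


@pytest.fixture(scope="module")
def model(small_truth):
    pes = observe_pes(small_truth, range(1955, 1990, 5),
                      ObservationConfig(seed=4), noise_sd=0.005)
    return fit_completeness_model(pes)


class TestAdjustCensus:
    def test_flat_completeness_divides_counts(self):
        c = _five_year_census(np.full(20, 95.0), np.full(20, 95.0))
        model = fit_completeness_model(
            [PESRecord("a", 1980, 0.95, s) for s in (0.2, 0.5, 0.8)])
        adj = adjust_census(c, model, sdi=0.5, sdi_group="high-middle")
        np.testing.assert_allclose(adj.adjusted, 100.0, rtol=1e-6)

    def test_unit_completeness_identity(self):
        c = _five_year_census(np.full(20, 50.0), np.full(20, 60.0))
        model = fit_completeness_model(
            [PESRecord("a", 1980, 1.0, s) for s in (0.2, 0.5, 0.8)])
        adj = adjust_census(c, model, sdi=0.5, sdi_group="high-middle")
        np.testing.assert_allclose(adj.adjusted, c.counts, rtol=1e-9)

    def test_scale_equivariance(self, model):
        f = np.linspace(500, 100, 20)
        c1 = _five_year_census(f, f)
        c2 = _five_year_census(7 * f, 7 * f)
        a1 = adjust_census(c1, model, 0.5, "middle")
        a2 = adjust_census(c2, model, 0.5, "middle")
        np.testing.assert_allclose(a2.adjusted, 7 * a1.adjusted, rtol=1e-12)

    def test_recovery_on_synthetic_undercount(self, small_truth, model):
        c = observe_census(small_truth, 1975,
                           ObservationConfig(age_grouping="five"))
        sdi = float(small_truth.sdi[25])
        adj = adjust_census(c, model, sdi, "middle")
        truth_total = small_truth.true_pop.total(1975)
        assert abs(adj.adjusted.sum() / truth_total - 1.0) < 0.02
        assert adj.drop_under5

    def test_high_sdi_uses_own_pes(self, model):
        c = _five_year_census(np.full(20, 90.0), np.full(20, 90.0))
        own = PESRecord("x", 1980, 0.9, 0.9)
        adj = adjust_census(c, model, 0.9, "high", own_pes=own)
        assert adj.completeness == 0.9
        assert not adj.drop_under5

    def test_outlier_refused(self, model):
        c = _five_year_census(np.full(20, 1.0), np.full(20, 1.0))
        c.outlier = True
        with pytest.raises(ValueError, match="outlier"):
            adjust_census(c, model, 0.5, "middle")


class TestJointScore:
    def test_smooth_equal_sex_population_scores_low(self):
        f = 1e5 * np.exp(-0.02 * np.arange(0, 100, 5))
        c = _five_year_census(f, f)
        scores = age_sex_joint_score(c)
        assert scores["joint_score"] < 1.0

    def test_perturbation_increases_score(self):
        f = 1e5 * np.exp(-0.02 * np.arange(0, 100, 5))
        base = age_sex_joint_score(_five_year_census(f, f))["joint_score"]
        f2 = f.copy()
        f2[6] *= 2.0
        bumped = age_sex_joint_score(_five_year_census(f2, f))["joint_score"]
        assert bumped > base

    def test_matches_hand_computed_toy_index(self):
        # 6 groups, hand-computed in the docstring arithmetic below
        f = np.array([100.0, 90.0, 80.0, 70.0, 60.0, 50.0])
        m = np.array([110.0, 90.0, 85.0, 70.0, 55.0, 50.0])
        c = _five_year_census(f, m)
        s = age_sex_joint_score(c)
        ar_f = 100 * 2 * f[1:-1] / (f[:-2] + f[2:])
        ar_m = 100 * 2 * m[1:-1] / (m[:-2] + m[2:])
        sr = 100 * m / f
        expected = (3 * np.mean(np.abs(np.diff(sr)))
                    + np.mean(np.abs(ar_m - 100))
                    + np.mean(np.abs(ar_f - 100)))
        assert s["joint_score"] == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_rejected(self):
        f = np.array([100.0, 0.0, 80.0, 70.0, 60.0, 50.0])
        with pytest.raises(ValueError):
            age_sex_joint_score(_five_year_census(f, f))


class TestHeapingCorrection:
    def test_feeney_fixed_point_on_smooth_counts(self):
        smooth = 1e5 * np.exp(-0.03 * np.arange(95))
        out = correct_heaping(smooth, "feeney")
        assert np.max(np.abs(out / smooth - 1.0)) < 1e-6

    @given(strength=st.floats(0.1, 0.5))
    @settings(max_examples=8, deadline=None)
    def test_totals_conserved_all_methods(self, strength):
        smooth = 1e5 * np.exp(-0.03 * np.arange(95))
        heaped = synthetic.apply_heaping(
            np.concatenate([smooth, [0.0]]), strength)[:95]
        fee = correct_heaping(heaped, "feeney")
        assert fee.sum() == pytest.approx(heaped.sum(), rel=1e-9)
        g5 = heaped.reshape(19, 5).sum(axis=1)
        for method in ("arriaga", "arriaga_strong"):
            out = correct_heaping(g5, method, age_start=np.arange(0, 95, 5))
            assert out.sum() == pytest.approx(g5.sum(), rel=1e-9)
            assert np.all(out >= 0)

    def test_arriaga_preserves_ten_year_totals(self):
        g5 = 1e4 * np.exp(-0.1 * np.arange(18))
        out = correct_heaping(g5, "arriaga", age_start=np.arange(0, 90, 5))
        t10_in = g5.reshape(9, 2).sum(axis=1)
        t10_out = out.reshape(9, 2).sum(axis=1)
        np.testing.assert_allclose(t10_out, t10_in, rtol=1e-12)

    def test_whipple_restored_on_heaped_census(self, small_truth):
        cfg = ObservationConfig(age_grouping="single",
                                heaping_strength=0.3)
        c = observe_census(small_truth, 1975, cfg)
        heaped = c.counts.sum(axis=0)[:95]
        w_before = whipple_index(heaped)
        w_after = whipple_index(correct_heaping(heaped, "feeney"))
        assert abs(w_after - 100) <= 0.2 * abs(w_before - 100)

    def test_wrong_grouping_rejected(self):
        with pytest.raises(ValueError):
            correct_heaping(np.ones(10), "feeney",
                            age_start=np.arange(0, 50, 5))
        with pytest.raises(ValueError):
            correct_heaping(np.ones(3), "arriaga",
                            age_start=np.arange(0, 15, 5))

    def test_selection_rule(self, small_truth):
        cfg = ObservationConfig(age_grouping="single",
                                heaping_strength=0.3)
        c = observe_census(small_truth, 1975, cfg)
        assert select_correction(c) == "feeney"
        smooth = observe_census(small_truth, 1975,
                                ObservationConfig(age_grouping="five"))
        assert select_correction(smooth) == "none"

    def test_decade_biased_heaping_scores_high_and_selects_arriaga(
            self, small_truth):
        # 0-over-5 digit preference distorts 5-year group totals, which
        # is what the joint score detects in grouped counts
        cfg = ObservationConfig(age_grouping="five",
                                heaping_strength=0.4,
                                heaping_decade_bias=1.0)
        c = observe_census(small_truth, 1975, cfg)
        score = age_sex_joint_score(c)["joint_score"]
        assert score > 20
        assert select_correction(c) in ("arriaga", "arriaga_strong")
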