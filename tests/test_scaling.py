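import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

import oxyscale as ox
from oxyscale.scaling import _ols


def _obs_with_norm(embryo_id, o2, temp, values, interval=10.0, t0=1.0):
    """Build an embryo whose normalized times equal ``values`` exactly."""
    times = {"membrane_reaches_yolk": t0, "trachea_fill": t0 + interval}
    for e, v in values.items():
        times[e] = t0 + v * interval
    return ox.EmbryoObservation(
        embryo_id=embryo_id,
        condition=ox.Condition(o2, temp),
        event_times=times,
        hatched=True,
    )


class TestNormalizeTimeline:
    def test_interior_event(self):
        obs = ox.EmbryoObservation(
            "a", ox.Condition(21, 22.5),
            {"membrane_reaches_yolk": 2.0, "heart_shaped_midgut": 14.0, "trachea_fill": 22.0},
            hatched=True,
        )
        nt = ox.normalize_timeline(obs)
        assert nt.normalized_times["heart_shaped_midgut"] == pytest.approx(0.6)
        assert nt.normalized_times["membrane_reaches_yolk"] == 0.0
        assert nt.normalized_times["trachea_fill"] == 1.0

    def test_pole_bud_maps_negative(self):
        obs = ox.EmbryoObservation(
            "a", ox.Condition(21, 22.5),
            {"pole_bud_appearance": 0.5, "membrane_reaches_yolk": 2.0, "trachea_fill": 22.0},
            hatched=True,
        )
        nt = ox.normalize_timeline(obs)
        assert nt.normalized_times["pole_bud_appearance"] == pytest.approx(-0.075)

    def test_missing_anchor_is_censoring_error(self):
        obs = ox.EmbryoObservation(
            "a", ox.Condition(21, 22.5), {"membrane_reaches_yolk": 2.0}, hatched=False
        )
        with pytest.raises(ox.CensoringError, match="trachea_fill"):
            ox.normalize_timeline(obs)

    def test_zero_interval_is_degenerate(self):
        obs = ox.EmbryoObservation(
            "a", ox.Condition(21, 22.5),
            {"membrane_reaches_yolk": 2.0, "trachea_fill": 2.0}, hatched=False,
        )
        with pytest.raises(ox.DegenerateDataError):
            ox.normalize_timeline(obs)

    @given(
        shift=st.floats(-5.0, 50.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_affine_invariance(self, shift, scale, complete_obs):
        base = ox.normalize_timeline(complete_obs).normalized_times
        moved = ox.EmbryoObservation(
            complete_obs.embryo_id,
            complete_obs.condition,
            {e: (t + 5.0) * scale + max(shift, 0.0) for e, t in complete_obs.event_times.items()},
            hatched=complete_obs.hatched,
        )
        out = ox.normalize_timeline(moved).normalized_times
        for e in base:
            assert out[e] == pytest.approx(base[e], abs=1e-9)


class TestEventRegression:
    def test_exact_line(self):
        ds = ox.Dataset(observations=[
            _obs_with_norm("a", 10.0, 27.5, {"amnioserosa_exposure": 0.50}),
            _obs_with_norm("b", 20.0, 27.5, {"amnioserosa_exposure": 0.60}),
            _obs_with_norm("c", 30.0, 27.5, {"amnioserosa_exposure": 0.70}),
        ])
        fit = ox.event_regression(ds, "amnioserosa_exposure", 27.5)
        assert fit.slope == pytest.approx(0.01, abs=1e-12)
        assert fit.intercept == pytest.approx(0.40, abs=1e-12)
        assert fit.sse == pytest.approx(0.0, abs=1e-20)
        assert fit.n == 3 and fit.pearson_r == pytest.approx(1.0)

    def test_constant_response_has_zero_slope(self):
        ds = ox.Dataset(observations=[
            _obs_with_norm(f"e{i}", o2, 27.5, {"amnioserosa_exposure": 0.5})
            for i, o2 in enumerate((10.0, 20.0, 30.0))
        ])
        fit = ox.event_regression(ds, "amnioserosa_exposure", 27.5)
        assert fit.slope == pytest.approx(0.0, abs=1e-15)
        assert fit.pearson_r == 0.0

    def test_ols_matches_independent_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.uniform(5, 35, size=12)
            y = rng.normal(0.5, 0.2, size=12)
            slope, intercept, sse, sxx, r = _ols(x, y)
            ref = sm.OLS(y, sm.add_constant(x)).fit()
            assert intercept == pytest.approx(ref.params[0], abs=1e-10)
            assert slope == pytest.approx(ref.params[1], abs=1e-10)
            assert sse == pytest.approx(ref.ssr, rel=1e-10)

    def test_insufficient_embryos(self):
        ds = ox.Dataset(observations=[
            _obs_with_norm("a", 10.0, 27.5, {"amnioserosa_exposure": 0.5}),
            _obs_with_norm("b", 20.0, 27.5, {"amnioserosa_exposure": 0.6}),
        ])
        with pytest.raises(ox.SampleSizeError):
            ox.event_regression(ds, "amnioserosa_exposure", 27.5)

    def test_single_oxygen_level_is_degenerate(self):
        ds = ox.Dataset(observations=[
            _obs_with_norm(f"e{i}", 21.0, 27.5, {"amnioserosa_exposure": 0.5 + 0.01 * i})
            for i in range(4)
        ])
        with pytest.raises(ox.DegenerateDesignError):
            ox.event_regression(ds, "amnioserosa_exposure", 27.5)


class TestSlopeComparison:
    def test_identical_fits_give_t_zero_p_one(self):
        fit = ox.LinearFit(slope=0.01, intercept=0.4, n=10, sse=0.02, sxx=400.0,
                           pearson_r=0.9, event="a", temperature_celsius=27.5)
        res = ox.compare_event_slopes(fit, fit)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)
        assert res.degrees_of_freedom == 16

    def test_matches_hand_computed_pooled_formula(self):
        fa = ox.LinearFit(slope=0.012, intercept=0.1, n=8, sse=0.004, sxx=300.0,
                          pearson_r=0.9, event="a")
        fb = ox.LinearFit(slope=-0.0025, intercept=0.7, n=7, sse=0.006, sxx=250.0,
                          pearson_r=-0.8, event="b")
        res = ox.compare_event_slopes(fa, fb)
        s2p = (0.004 + 0.006) / (8 + 7 - 4)
        t_expected = (0.012 + 0.0025) / math.sqrt(s2p * (1 / 300.0 + 1 / 250.0))
        assert res.t_statistic == pytest.approx(t_expected, abs=1e-12)
        assert res.degrees_of_freedom == 11
        assert 0.0 < res.p_raw < 1.0

    def test_well_separated_slopes_give_tiny_p(self):
        fa = ox.LinearFit(slope=0.01, intercept=0.4, n=20, sse=1e-8, sxx=500.0, pearson_r=1.0)
        fb = ox.LinearFit(slope=-0.0025, intercept=0.6, n=20, sse=1e-8, sxx=500.0, pearson_r=-1.0)
        res = ox.compare_event_slopes(fa, fb)
        assert abs(res.t_statistic) > 100
        assert res.p_raw < 1e-12

    def test_zero_pooled_variance_with_unequal_slopes(self):
        fa = ox.LinearFit(slope=0.01, intercept=0.4, n=5, sse=0.0, sxx=100.0, pearson_r=1.0)
        fb = ox.LinearFit(slope=0.02, intercept=0.4, n=5, sse=0.0, sxx=100.0, pearson_r=1.0)
        res = ox.compare_event_slopes(fa, fb)
        assert math.isinf(res.t_statistic)
        assert res.p_raw == 0.0


class TestBonferroni:
    def test_single_test_unchanged(self):
        t = ox.PairwiseScalingTest("a", "b", 27.5, 2.0, 10, 0.03)
        (out,) = ox.bonferroni([t])
        assert out.p_bonferroni == pytest.approx(0.03)
        assert out.m_comparisons == 1

    def test_capped_at_one(self):
        tests = [ox.PairwiseScalingTest("a", "b", 27.5, 1.0, 10, 0.2)] * 10
        out = ox.bonferroni(tests)
        assert all(t.p_bonferroni == 1.0 for t in out)

    def test_scaling_by_family_size(self):
        tests = [ox.PairwiseScalingTest("a", "b", 27.5, 1.0, 10, 0.001)] * 36
        out = ox.bonferroni(tests)
        assert out[0].p_bonferroni == pytest.approx(0.036)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            ox.bonferroni([])


class TestFindInversion:
    def test_crossing_of_head_and_gut_lines(self):
        # lines 0.50 + 0.01*(O-21) and 0.60 - 0.0025*(O-21) cross at O = 29
        fa = ox.LinearFit(slope=0.01, intercept=0.50 - 0.01 * 21, n=10, sse=0.0,
                          sxx=100.0, pearson_r=1.0, event="cephalic_lobes_even")
        fb = ox.LinearFit(slope=-0.0025, intercept=0.60 + 0.0025 * 21, n=10, sse=0.0,
                          sxx=100.0, pearson_r=-1.0, event="heart_shaped_midgut")
        inv = ox.find_inversion(fa, fb, observed_range=(10.0, 29.0))
        assert inv.crossing_oxygen_percent == pytest.approx(29.0, abs=1e-9)
        assert inv.within_observed_range  # closed interval: the edge counts
        assert not inv.parallel

    def test_identical_lines_are_parallel_result_not_error(self):
        f = ox.LinearFit(slope=0.01, intercept=0.2, n=10, sse=0.0, sxx=100.0, pearson_r=1.0)
        inv = ox.find_inversion(f, f)
        assert inv.parallel and inv.crossing_oxygen_percent is None
        assert not inv.within_observed_range

    def test_extrapolated_crossing_flagged(self):
        fa = ox.LinearFit(slope=0.01, intercept=0.0, n=10, sse=0.0, sxx=100.0, pearson_r=1.0)
        fb = ox.LinearFit(slope=0.005, intercept=0.175, n=10, sse=0.0, sxx=100.0, pearson_r=1.0)
        inv = ox.find_inversion(fa, fb, observed_range=(10.0, 29.0))
        assert inv.crossing_oxygen_percent == pytest.approx(35.0)
        assert not inv.within_observed_range


class TestScalingAnalysis:
    def test_full_analysis_structure(self):
        ds = ox.generate_dataset(ox.default_config(n_per_condition=8, noise_sd=0.3, seed=2))
        res = ox.scaling_analysis(ds, 27.5)
        assert set(res.fits) == set(ox.scaling.REGRESSABLE_EVENTS)
        assert len(res.tests) == 21  # all pairs of 7 regressable events
        assert all(t.m_comparisons == 21 for t in res.tests)
        assert all(0.0 <= t.p_raw <= 1.0 and t.p_bonferroni <= 1.0 for t in res.tests)
        assert len(res.inversions) == 21

    def test_recovers_configured_heterochrony_signs(self):
        ds = ox.generate_dataset(ox.default_config(n_per_condition=20, noise_sd=0.25, seed=4))
        res = ox.scaling_analysis(ds, 22.5)
        assert res.fits["cephalic_lobes_even"].slope > 0
        assert res.fits["heart_shaped_midgut"].slope < 0
        assert res.fits["pole_bud_appearance"].slope < 0
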