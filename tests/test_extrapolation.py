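"""Piecewise joins, mortality floors, averaging, RMST and hazard curves."""

import numpy as np
import pytest

from interpsurv import (
    CureModel,
    EventData,
    ModelAverage,
    ParametricModel,
    apply_background_mortality,
    average_models,
    build_piecewise,
    evaluate,
    hazard_curve,
    kaplan_meier,
    rmst,
    solve,
)
from interpsurv.exceptions import (
    LifeTableCoverageError,
    ParameterError,
    PointMonotonicityError,
    PointOrderingError,
)


class TestBuildPiecewise:
    def test_conditional_conversion_and_exact_interpolation(self):
        pw = build_piecewise((7.7, 0.5), "gompertz", [(17.0, 0.25), (60.0, 0.10)])
        # conditional points are (9.3, 0.5) and (52.3, 0.2)
        assert pw.tail.survival(9.3) == pytest.approx(0.5, abs=1e-10)
        assert pw.tail.survival(52.3) == pytest.approx(0.2, abs=1e-10)
        assert pw.survival(17.0) == pytest.approx(0.25, abs=1e-8)
        assert pw.survival(60.0) == pytest.approx(0.10, abs=1e-8)

    def test_continuity_at_join(self):
        pw = build_piecewise((7.7, 0.5), "gompertz", [(17.0, 0.25), (60.0, 0.10)])
        assert pw.survival(7.7) == pytest.approx(0.5, abs=1e-12)
        assert pw.survival(7.7 - 1e-9) == pytest.approx(0.5, abs=1e-6)
        assert pw.survival(7.7 + 1e-9) == pytest.approx(0.5, abs=1e-6)

    def test_degenerate_join_matches_plain_model(self):
        pts = [(2.0, 0.7), (9.0, 0.2)]
        pw = build_piecewise((0.0, 1.0), "weibull", pts)
        plain = solve("weibull", pts).model
        t = np.linspace(0.0, 20.0, 50)
        assert np.allclose(pw.survival(t), plain.survival(t), atol=1e-12)

    def test_point_before_join_is_ordering_error(self):
        with pytest.raises(PointOrderingError):
            build_piecewise((7.7, 0.5), "weibull", [(5.0, 0.6), (60.0, 0.1)])

    def test_point_above_anchor_is_monotonicity_error(self):
        with pytest.raises(PointMonotonicityError):
            build_piecewise((7.7, 0.5), "weibull", [(17.0, 0.6), (60.0, 0.1)])

    def test_km_prefix_anchor(self, fixtures):
        km = kaplan_meier(fixtures.km_like_data)
        pw = build_piecewise(km, "gompertz", list(fixtures.piecewise_points), t0=7.7)
        assert pw.anchor == pytest.approx(0.5)
        assert pw.survival(3.0) == pytest.approx(
            km.survival[np.searchsorted(km.times, 3.0, side="right") - 1]
        )
        assert pw.survival(60.0) == pytest.approx(0.10, abs=1e-8)

    def test_cure_tail_plateau(self):
        pw = build_piecewise(
            (7.7, 0.5), "exponential", [(17.0, 0.25)], pi=0.3
        )
        assert pw.survival(17.0) == pytest.approx(0.25, abs=1e-10)
        # overall plateau is anchor * pi
        assert pw.survival(1e5) == pytest.approx(0.5 * 0.3, abs=1e-6)


class TestBackgroundMortality:
    def test_floor_inactive_when_inner_hazard_dominates(self, flat_life_table):
        inner = ParametricModel("exponential", (0.10,), time_unit="years")
        adj = apply_background_mortality(inner, flat_life_table, 40, "female",
                                         horizon=30.0)
        t = np.linspace(0.0, 30.0, 200)
        assert np.allclose(adj.survival(t), inner.survival(t), atol=1e-12)

    def test_flat_floor_dominates_small_inner_hazard(self, flat_life_table):
        inner = ParametricModel("exponential", (0.001,), time_unit="years")
        adj = apply_background_mortality(inner, flat_life_table, 40, "female",
                                         horizon=30.0)
        t = np.linspace(0.0, 30.0, 200)
        # analytic max-hazard solution: constant hazard 0.02
        assert np.max(np.abs(adj.survival(t) - np.exp(-0.02 * t))) < 1e-5

    def test_decaying_gompertz_tail_reaches_population_hazard(self, flat_life_table):
        inner = ParametricModel("gompertz", (-0.3, 0.4), time_unit="years")
        adj = apply_background_mortality(inner, flat_life_table, 40, "female",
                                         horizon=40.0)
        t = np.linspace(0.1, 40.0, 100)
        assert np.all(adj.hazard(t) >= 0.02 - 1e-12)
        assert adj.survival(40.0) < inner.survival(40.0)
        # fine-grid numerical oracle for the max-hazard integral
        fine = np.linspace(0.0, 40.0, 200001)
        h = np.maximum(inner.hazard(fine), 0.02)
        H = np.concatenate([[0.0], np.cumsum((h[1:] + h[:-1]) / 2 * np.diff(fine))])
        oracle = np.exp(-np.interp(t, fine, H))
        assert np.max(np.abs(adj.survival(t) - oracle)) < 1e-5

    def test_adjusted_never_above_inner(self, flat_life_table):
        inner = ParametricModel("weibull", (0.7, 10.0), time_unit="years")
        adj = apply_background_mortality(inner, flat_life_table, 50, "male",
                                         horizon=30.0)
        t = np.linspace(0.0, 30.0, 300)
        assert np.all(adj.survival(t) <= np.asarray(inner.survival(t)) + 1e-15)

    def test_horizon_beyond_table_is_coverage_error(self, flat_life_table):
        inner = ParametricModel("exponential", (0.01,), time_unit="years")
        with pytest.raises(LifeTableCoverageError):
            apply_background_mortality(inner, flat_life_table, 90, "female",
                                       horizon=30.0)

    def test_time_unit_conversion(self, flat_life_table):
        # same model expressed in months: hazard floor 0.02/12 per month
        inner = ParametricModel("exponential", (0.0001,), time_unit="months")
        adj = apply_background_mortality(inner, flat_life_table, 40, "female",
                                         horizon=120.0)
        assert adj.survival(120.0) == pytest.approx(
            np.exp(-(0.02 / 12) * 120.0), rel=1e-4
        )


class TestAverageAndEvaluate:
    def test_average_of_identical_models_is_identity(self):
        m = ParametricModel("exponential", (0.5,))
        assert average_models([m, m], 3.0) == pytest.approx(m.survival(3.0))

    def test_average_by_definition(self):
        m1 = ParametricModel("exponential", (1.0,))
        m2 = ParametricModel("exponential", (3.0,))
        expected = (np.exp(-1.0) + np.exp(-3.0)) / 2.0
        assert average_models([m1, m2], 1.0) == pytest.approx(expected, abs=1e-12)

    def test_average_at_zero_is_one(self):
        models = [ParametricModel("weibull", (1.3, 2.0)),
                  CureModel(0.2, ParametricModel("exponential", (0.4,)))]
        assert average_models(models, 0.0) == 1.0

    def test_empty_average_rejected(self):
        with pytest.raises(ParameterError):
            ModelAverage(())

    def test_evaluate_dispatch(self):
        m = ParametricModel("exponential", (2.0,))
        assert evaluate(m, 3.0) == pytest.approx(np.exp(-6.0))


class TestRMST:
    def test_exponential_closed_form(self):
        r = rmst(ParametricModel("exponential", (1.0,)), 5.0)
        assert r.value == pytest.approx(1.0 - np.exp(-5.0), abs=1e-6)

    def test_long_horizon_approaches_mean(self):
        r = rmst(ParametricModel("exponential", (0.5,)), 40.0)
        assert r.value == pytest.approx(2.0, abs=1e-4)

    def test_cure_mixture_linearity(self):
        cure = CureModel(0.4, ParametricModel("exponential", (1.0,)))
        r = rmst(cure, 10.0)
        assert r.value == pytest.approx(0.4 * 10.0 + 0.6 * (1.0 - np.exp(-10.0)),
                                        abs=1e-5)

    def test_average_rmst_is_mean_of_member_rmsts(self):
        m1 = ParametricModel("exponential", (0.3,))
        m2 = ParametricModel("weibull", (1.5, 4.0))
        avg = ModelAverage((m1, m2))
        lhs = rmst(avg, 12.0).value
        rhs = (rmst(m1, 12.0).value + rmst(m2, 12.0).value) / 2.0
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_monotone_in_tau_and_grid_refinement(self):
        m = ParametricModel("loglogistic", (1.5, 3.0))
        values = [rmst(m, tau).value for tau in (1.0, 5.0, 10.0, 20.0)]
        assert np.all(np.diff(values) > 0)
        coarse = rmst(m, 10.0).value
        fine = rmst(m, 10.0, n_grid=40001).value
        assert abs(fine - coarse) / coarse < 1e-6

    def test_life_year_conversion(self):
        r = rmst(ParametricModel("exponential", (0.05,)), 24.0)
        assert r.to_years("months") == pytest.approx(r.value / 12.0)


class TestHazardCurve:
    def test_exponential_flat(self):
        th = hazard_curve(ParametricModel("exponential", (0.3,)), np.linspace(0.5, 20, 40))
        assert np.allclose(th[:, 1], 0.3)

    def test_gompertz_increasing(self):
        th = hazard_curve(ParametricModel("gompertz", (0.2, 0.1)), np.linspace(0.5, 10, 40))
        assert np.all(np.diff(th[:, 1]) > 0)

    def test_mortality_adjusted_hazard_floored(self, flat_life_table):
        inner = ParametricModel("gompertz", (-0.3, 0.4), time_unit="years")
        adj = apply_background_mortality(inner, flat_life_table, 40, "female",
                                         horizon=40.0)
        th = hazard_curve(adj, np.linspace(0.5, 39.5, 60))
        assert np.all(th[:, 1] >= 0.02 - 1e-12)

    def test_numeric_fallback_matches_analytic(self):
        m = ParametricModel("weibull", (1.7, 5.0))

        class Wrapper:  # survival-only object exercises the finite-difference path
            def survival(self, t):
                return m.survival(t)

        grid = np.linspace(0.5, 15.0, 30)
        numeric = hazard_curve(Wrapper(), grid)
        analytic = hazard_curve(m, grid)
        assert np.allclose(numeric[:, 1], analytic[:, 1], rtol=1e-6)
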