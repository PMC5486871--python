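"""Aggregation, Weber/Fechner fitting, probit averaging, bias comparison."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from corrlaw.lawfit import (
    JndPoint,
    aggregate_jnds,
    apply_range_constraint,
    base_k_to_weber_slope,
    compare_biases,
    fit_fechner,
    fit_weber_line,
    outlier_observer_ids,
    probit_mean_bias,
    runs_from_jnd_table,
    jnd_table_from_runs,
    weber_slope_to_base_k,
)
from corrlaw.observer import ObserverParams, theoretical_jnd
from corrlaw.staircase import StaircaseRun


def _run(base, direction, jnd, obs=0):
    return StaircaseRun(base_r=base, direction=direction, trials=[], jnd=jnd,
                        converged=True, n_trials=0, observer_id=obs)


def _point(base, direction, jnd, sd=0.0, n=1):
    sign = 0.5 if direction == "above" else -0.5
    test = base + jnd if direction == "above" else base - jnd
    return JndPoint(base_r=base, direction=direction, jnd=jnd,
                    adjusted_r=base + sign * jnd, test_mean=test,
                    test_sd=sd, n_observers=n)


class TestAggregate:
    def test_single_observer_passthrough(self):
        pts = aggregate_jnds([_run(0.3, "above", 0.12)])
        assert pts[0].jnd == pytest.approx(0.12)
        assert pts[0].adjusted_r == pytest.approx(0.36)

    def test_geometric_mean(self):
        pts = aggregate_jnds([_run(0.3, "above", 0.1, 0),
                              _run(0.3, "above", 0.4, 1)])
        assert pts[0].jnd == pytest.approx(0.2)  # sqrt(0.04)

    def test_adjusted_r_signed_convention(self):
        pts = aggregate_jnds([_run(0.6, "above", 0.1), _run(0.6, "below", 0.1)])
        by_dir = {p.direction: p for p in pts}
        assert by_dir["above"].adjusted_r == pytest.approx(0.65)
        assert by_dir["below"].adjusted_r == pytest.approx(0.55)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            aggregate_jnds([])
        with pytest.raises(ValueError):
            aggregate_jnds([_run(0.3, "above", 0.0)])


class TestRangeConstraint:
    def test_drops_cell_crossing_zero(self):
        # below at base 0.3: test mean 0.15, sd 0.07 -> 0.15 - 2.5*0.07 < 0
        p = _point(0.3, "below", 0.15, sd=0.07, n=20)
        assert apply_range_constraint([p]) == []

    def test_keeps_interior_cell(self):
        p = _point(0.5, "above", 0.1, sd=0.05, n=20)
        assert apply_range_constraint([p]) == [p]

    def test_zero_sd_kept_unless_mean_outside(self):
        inside = _point(0.9, "above", 0.05, sd=0.0)
        assert apply_range_constraint([inside]) == [inside]


class TestWeberFit:
    def test_exact_recovery_from_noiseless_line(self):
        k, b = 0.21, 0.90
        pts = []
        for r in np.arange(0.3, 0.91, 0.1):
            jnd = k * (1 / b - r)
            pts.append(JndPoint(r, "above", jnd, adjusted_r=r,
                                test_mean=r + jnd, test_sd=0.0, n_observers=1))
        fit = fit_weber_line(pts)
        assert fit.k == pytest.approx(k, abs=1e-12)
        assert fit.b_disc == pytest.approx(b, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_bias_from_reported_slope_and_intercept(self):
        # slope -0.20 with y-intercept 0.23 corresponds to bias 0.87
        pts = [JndPoint(r, "above", 0.23 - 0.20 * r, adjusted_r=r,
                        test_mean=0.5, test_sd=0.0, n_observers=1)
               for r in (0.1, 0.4, 0.8)]
        fit = fit_weber_line(pts)
        assert round(fit.b_disc, 2) == 0.87

    def test_ci_covers_truth_with_noise(self, rng):
        k, b = 0.2, 0.9
        x = np.linspace(0.05, 0.95, 15)
        y = k * (1 / b - x) + rng.normal(0, 0.004, x.size)
        pts = [JndPoint(xi, "above", yi, adjusted_r=xi, test_mean=0.5,
                        test_sd=0.0, n_observers=1)
               for xi, yi in zip(x, y)]
        fit = fit_weber_line(pts)
        assert fit.ci_k[0] <= k <= fit.ci_k[1]
        assert fit.ci_b[0] <= b <= fit.ci_b[1]

    def test_degenerate_inputs_rejected(self):
        p = _point(0.3, "above", 0.1)
        with pytest.raises(ValueError):
            fit_weber_line([p])
        with pytest.raises(ValueError):
            fit_weber_line([p, p])

    def test_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm

        x = np.linspace(0.1, 0.9, 12)
        y = 0.25 - 0.22 * x + rng.normal(0, 0.01, x.size)
        pts = [JndPoint(xi, "above", yi, adjusted_r=xi, test_mean=0.5,
                        test_sd=0.0, n_observers=1)
               for xi, yi in zip(x, y)]
        fit = fit_weber_line(pts)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.k == pytest.approx(-ref.params[1], abs=1e-10)
        assert fit.y_intercept == pytest.approx(ref.params[0], abs=1e-10)
        assert fit.r_squared == pytest.approx(ref.rsquared, abs=1e-10)
        lo, hi = ref.conf_int()[1]
        assert fit.ci_k[0] == pytest.approx(-hi, abs=1e-8)
        assert fit.ci_k[1] == pytest.approx(-lo, abs=1e-8)


class TestSlopeParametrization:
    def test_adjusted_space_slope_mapping_is_exact(self):
        # theoretical thresholds plotted at r_A fall on an exact line whose
        # slope is k0/(1 - k0/2), identically for both directions
        obs = ObserverParams.from_weber(0.9, 0.21)
        pts = []
        for r in np.arange(0.0, 0.91, 0.1):
            for direction in ("above", "below"):
                if direction == "below" and r < 0.3:
                    continue
                jnd = theoretical_jnd(r, obs, direction)
                sign = 0.5 if direction == "above" else -0.5
                pts.append(JndPoint(r, direction, jnd, adjusted_r=r + sign * jnd,
                                    test_mean=0.5, test_sd=0.0, n_observers=1))
        fit = fit_weber_line(pts)
        assert fit.k == pytest.approx(base_k_to_weber_slope(0.21), abs=1e-10)
        assert fit.b_disc == pytest.approx(0.9, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert weber_slope_to_base_k(fit.k) == pytest.approx(0.21, abs=1e-10)

    def test_mappings_are_inverses(self):
        for k in (0.1, 0.21, 0.35):
            assert weber_slope_to_base_k(
                base_k_to_weber_slope(k)
            ) == pytest.approx(k, abs=1e-14)


class TestFechnerFit:
    def test_self_consistency_on_noiseless_levels(self):
        # invert g(r) = level in closed form, then refit
        rs = {lv: (1 - math.exp(lv * math.log(1 - 0.9))) / 0.9
              for lv in (0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875)}
        fit = fit_fechner(rs)
        assert fit.b_est == pytest.approx(0.9, abs=1e-4)
        assert fit.rmse <= 1e-6

    def test_veridical_levels_drive_bias_to_lower_bound(self):
        levels = {lv: lv for lv in (0.125, 0.25, 0.5, 0.75, 0.875)}
        fit = fit_fechner(levels)
        assert fit.b_est <= 2e-4
        assert fit.rmse <= 1e-4

    def test_matches_independent_dense_grid(self, rng):
        # independent oracle: brute-force 1e-6-resolution scan
        levels = {0.25: 0.55, 0.5: 0.78, 0.75: 0.91}
        fit = fit_fechner(levels)
        grid = np.arange(1e-6, 0.99, 1e-6)
        rs = np.array(sorted(levels.values()))
        lv = np.array(sorted(levels))
        sse = (
            (np.log1p(-np.outer(grid, rs)) / np.log1p(-grid)[:, None] - lv)
            ** 2
        ).sum(axis=1)
        assert fit.b_est == pytest.approx(grid[sse.argmin()], abs=2e-6)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            fit_fechner({0.5: 0.7})
        with pytest.raises(ValueError):
            fit_fechner({0.25: 0.5, 0.75: 0.5})


class TestProbitAveraging:
    def test_identity_on_equal_biases(self):
        mean, _ = probit_mean_bias([0.5, 0.5])
        assert mean == pytest.approx(0.5, abs=1e-12)

    def test_hand_computed_pair(self):
        mean, _ = probit_mean_bias([0.8, 0.95])
        expected = norm.cdf((norm.ppf(0.8) + norm.ppf(0.95)) / 2)
        assert mean == pytest.approx(expected, abs=1e-12)
        assert mean == pytest.approx(0.8931, abs=1e-4)

    def test_cap_applied(self):
        mean, _ = probit_mean_bias([0.999, 0.999])
        assert mean == pytest.approx(0.99, abs=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            probit_mean_bias([0.5, 1.0])


class TestCompareBiases:
    def test_identical_vectors(self):
        res = compare_biases([0.9, 0.8, 0.85], [0.9, 0.8, 0.85])
        assert res.t_stat == 0.0
        assert res.mean_difference == 0.0

    def test_detects_probit_offset(self, rng):
        z = rng.normal(1.2, 0.15, 30)
        bd = norm.cdf(z + 0.2)
        be = norm.cdf(z)
        res = compare_biases(bd, be)
        assert res.p_value < 1e-6
        assert res.mean_difference > 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_biases([0.9], [0.9, 0.8])


def test_outlier_observer_rule():
    values = {i: 0.9 + 0.001 * i for i in range(10)}
    assert outlier_observer_ids(values) == set()
    values[99] = 0.2
    assert outlier_observer_ids(values) == {99}


def test_jnd_table_roundtrip():
    runs = [_run(0.3, "above", 0.12, 0), _run(0.6, "below", 0.08, 1)]
    table = jnd_table_from_runs(runs)
    back = runs_from_jnd_table(table)
    assert [(r.base_r, r.direction, r.jnd, r.observer_id) for r in back] == [
        (0.3, "above", 0.12, 0), (0.6, "below", 0.08, 1)
    ]
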