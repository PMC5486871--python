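"""Entropy model: density, ellipse geometry, residual bias, entropy links."""

import math

import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.stats import multivariate_normal

from corrlaw.entropy import (
    K1_HALF_MAX,
    TheoryParams,
    bias_from_residual,
    bigauss_density,
    bits_from_k,
    differential_entropy,
    ellipse_area,
    fechner_vs_entropy_rmse,
    isofraction_width,
    k_from_bits,
    magnitude_from_width,
    predicted_bias_for_sigma,
    residual_from_bias,
    unequal_sigma_jnd,
    unequal_sigma_magnitude,
)
from corrlaw.observer import perceived_magnitude

PARAM_GRID = [
    (0.0, 0.2, 1.0), (0.3, 0.2, 0.5), (0.5, 1.0, 2.0),
    (0.8, 0.5, 1.0), (0.95, 0.2, 5.0),
]


class TestDensity:
    def test_standard_normal_peak(self):
        assert bigauss_density(0, 0) == pytest.approx(1 / (2 * math.pi))

    def test_matches_scipy_multivariate_normal(self):
        for r, sx, kappa in PARAM_GRID:
            sy = kappa * sx
            cov = [[sx**2, r * sx * sy], [r * sx * sy, sy**2]]
            ref = multivariate_normal(mean=[0.1, -0.2], cov=cov)
            for pt in [(0.0, 0.0), (0.3, -0.5), (1.0, 1.0)]:
                assert bigauss_density(
                    pt[0], pt[1], 0.1, -0.2, sx, sy, r
                ) == pytest.approx(ref.pdf(pt), rel=1e-12)

    def test_integrates_to_one(self):
        total, _ = dblquad(
            lambda y, x: bigauss_density(x, y, 0, 0, 0.5, 0.8, 0.6),
            -5, 5, lambda x: -7, lambda x: 7, epsabs=1e-9,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_point_symmetry(self):
        assert bigauss_density(1.3, 0.4, 0.5, 0.5, 1, 1, 0.7) == pytest.approx(
            bigauss_density(-0.3, 0.6, 0.5, 0.5, 1, 1, 0.7), rel=1e-12
        )

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            bigauss_density(0, 0, r=1.0)


class TestIsofractionWidth:
    def test_equal_sigma_reduction(self):
        # kappa = 1 collapses to 2 sqrt(2) K1 sigma sqrt(1 - r)
        for r in np.linspace(0, 0.99, 12):
            w = isofraction_width(r, 0.2, 1.0, K1_HALF_MAX)
            assert w == pytest.approx(
                2 * math.sqrt(2) * K1_HALF_MAX * 0.2 * math.sqrt(1 - r),
                rel=1e-12,
            )

    def test_zero_correlation_equal_sigma(self):
        assert isofraction_width(0.0, 0.3, 1.0, 1.0) == pytest.approx(
            2 * math.sqrt(2) * 0.3
        )

    def test_contour_search_oracle(self):
        # independent oracle: semi-minor axis from the eigenstructure of the
        # quadratic form q(x, y) = K1^2
        for r, sx, kappa in PARAM_GRID:
            for K1 in (0.5, K1_HALF_MAX, 1.2):
                sy = kappa * sx
                M = np.array(
                    [[1 / sx**2, -r / (sx * sy)],
                     [-r / (sx * sy), 1 / sy**2]]
                ) / (2 * (1 - r**2))
                w_oracle = 2 * math.sqrt(K1**2 / np.linalg.eigvalsh(M)[-1])
                assert abs(
                    isofraction_width(r, sx, kappa, K1) - w_oracle
                ) <= 1e-6

    def test_extreme_anisotropy_limits(self):
        # kappa -> 0: width tends to 2 sqrt(2) K1 sigma_y sqrt(1 - r^2);
        # kappa -> inf: same form with sigma_x
        for r in (0.0, 0.5, 0.9):
            sx = 0.4
            kappa = 1e-3
            expect = 2 * math.sqrt(2) * K1_HALF_MAX * (kappa * sx) * math.sqrt(
                1 - r**2
            )
            assert isofraction_width(r, sx, kappa) == pytest.approx(
                expect, rel=1e-4
            )
            kappa = 1e3
            expect = 2 * math.sqrt(2) * K1_HALF_MAX * sx * math.sqrt(1 - r**2)
            assert isofraction_width(r, sx, kappa) == pytest.approx(
                expect, rel=1e-4
            )

    def test_vanishes_at_perfect_correlation(self):
        assert isofraction_width(1.0, 0.2, 1.0) == 0.0


class TestResidualBias:
    @pytest.mark.parametrize("c, b", [(0.0, 1.0), (1.0, 0.5)])
    def test_known_values(self, c, b):
        assert bias_from_residual(c) == pytest.approx(b)

    def test_roundtrip(self):
        for b in (0.3, 0.7, 0.95):
            assert bias_from_residual(residual_from_bias(b)) == pytest.approx(b)

    def test_sigma_scaling_prediction(self):
        # calibrate at sd 0.2 / bias 0.90, rescale to the uniform sd 0.29
        assert round(predicted_bias_for_sigma(0.90, 0.2, 0.29), 2) == 0.95

    def test_theory_params_composites(self):
        tp = TheoryParams(sigma_x=0.2, sigma_y=0.2, w_res=0.1)
        assert tp.kappa == 1.0
        assert tp.b == pytest.approx(bias_from_residual(tp.c))
        # b depends on K1 only through c: same c, different K1, same b
        tp2 = TheoryParams(K1=1.5, sigma_x=0.2, sigma_y=0.2,
                           w_res=0.1 * 1.5 / K1_HALF_MAX)
        assert tp2.c == pytest.approx(tp.c)
        assert tp2.b == pytest.approx(tp.b)

    def test_width_route_equals_fechner(self):
        r = np.linspace(0, 1, 20)
        np.testing.assert_allclose(
            magnitude_from_width(r, 0.9), perceived_magnitude(r, 0.9)
        )
        with pytest.raises(ValueError):
            magnitude_from_width(0.5, 1.0)  # zero residual diverges


class TestDifferentialEntropy:
    def test_standard_normal_value(self):
        assert differential_entropy(1, 1, 0) == pytest.approx(
            math.log(2 * math.pi * math.e), abs=1e-12
        )

    def test_quadrature_oracle(self):
        for sx, sy, r in [(1, 1, 0), (0.2, 0.2, 0.5), (0.5, 1.5, 0.8)]:
            f = lambda y, x: bigauss_density(x, y, 0, 0, sx, sy, r)
            H, _ = dblquad(
                lambda y, x: -f(y, x) * math.log(f(y, x)),
                -8 * sx, 8 * sx, lambda x: -8 * sy, lambda x: 8 * sy,
                epsabs=1e-9,
            )
            assert abs(H - differential_entropy(sx, sy, r)) <= 1e-5

    def test_monotone_decreasing_in_correlation(self):
        rs = np.linspace(0, 0.99, 30)
        hs = [differential_entropy(0.2, 0.2, r) for r in rs]
        assert np.all(np.diff(hs) < 0)

    def test_divergence_signaled(self):
        with pytest.raises(ValueError):
            differential_entropy(1, 1, 1.0)

    def test_dot_count_scaling(self):
        assert differential_entropy(0.2, 0.2, 0.5, n=100) == pytest.approx(
            100 * differential_entropy(0.2, 0.2, 0.5), rel=1e-12
        )


class TestEllipseArea:
    def test_zero_correlation(self):
        assert ellipse_area(0.0, 0.3, 0.4, 1.1) == pytest.approx(
            2 * math.pi * 0.3 * 0.4 * 1.1**2
        )

    def test_entropy_area_identity(self):
        # H(r) = n ln(A e / K1^2) exactly
        for r in (0.0, 0.5, 0.9):
            for sx, sy, K1, n in [(0.3, 0.7, 1.1, 5), (0.2, 0.2, 0.5, 1)]:
                A = ellipse_area(r, sx, sy, K1)
                H = differential_entropy(sx, sy, r, n=n)
                assert abs(H - n * math.log(A * math.e / K1**2)) <= 1e-12

    def test_area_ratio_closed_form(self):
        ratio = ellipse_area(0.8, 0.2, 0.2, 1.0) / ellipse_area(0.0, 0.2, 0.2, 1.0)
        assert ratio == pytest.approx(0.6)


class TestUnequalSigmaForms:
    def test_endpoints(self):
        assert unequal_sigma_magnitude(0.0, 0.9) == 0.0
        assert unequal_sigma_magnitude(1.0, 0.9) == pytest.approx(1.0)

    def test_known_value(self):
        # ln(0.676)/ln(0.1)
        assert unequal_sigma_magnitude(0.6, 0.9) == pytest.approx(
            math.log(0.676) / math.log(0.1), abs=1e-12
        )
        assert unequal_sigma_magnitude(0.6, 0.9) == pytest.approx(0.17005, abs=1e-4)

    def test_jnd_is_fechner_consequence(self):
        # dg/dr * JND must be constant in r under the shared-bias link
        b, kp = 0.9, 0.1
        rs = np.linspace(0.1, 0.95, 30)
        h = 1e-7
        prods = []
        for r in rs:
            dg = (unequal_sigma_magnitude(r + h, b)
                  - unequal_sigma_magnitude(r - h, b)) / (2 * h)
            prods.append(dg * unequal_sigma_jnd(r, kp, b))
        prods = np.asarray(prods)
        assert np.ptp(prods) / prods.mean() <= 1e-3

    def test_divergence_at_zero(self):
        with pytest.raises(ValueError):
            unequal_sigma_jnd(0.0, 0.1, 0.9)


class TestInformationLink:
    def test_inversion(self):
        # k = 0.21 at b = 0.90 corresponds to I75 = 0.21/2.302585 nats
        i75 = bits_from_k(0.21, 0.90)
        assert i75 == pytest.approx(0.0912, abs=1e-4)
        assert k_from_bits(i75, 0.90) == pytest.approx(0.21, abs=1e-12)

    def test_small_bias_limit(self):
        assert k_from_bits(0.1, 1e-12) == pytest.approx(0.0, abs=1e-12)

    def test_proportionality_across_bias(self):
        i75 = 0.09
        for b in (0.3, 0.6, 0.9):
            assert k_from_bits(i75, b) / (-math.log1p(-b)) == pytest.approx(i75)


class TestFechnerVsEntropy:
    def test_rmse_magnitude_and_sign_pattern(self):
        b2, rmse = fechner_vs_entropy_rmse(0.90)
        assert 0.03 < rmse < 0.05
        r = np.linspace(0, 1, 101)
        diff = perceived_magnitude(r, 0.90) - unequal_sigma_magnitude(r, b2)
        # Fechner curve higher at low r, lower at high r
        assert diff[10] > 0
        assert diff[90] < 0

    def test_families_genuinely_differ(self):
        _, rmse = fechner_vs_entropy_rmse(0.5)
        assert rmse > 0
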