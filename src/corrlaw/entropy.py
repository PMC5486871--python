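"""Entropy-based account of correlation perception.

The theoretical model treats the dot cloud as samples from a bivariate
gaussian density and proposes that perceived correlation tracks the
log-width of an *isofraction ellipse* — the level set where the density
falls to a fixed fraction exp(-K1^2) of its peak.  With equal marginal
sds the ellipse width is proportional to sqrt(1 - r); adding a residual
perceptual width w_res (noise/blur floor) and normalizing g(0) = 0,
g(1) = 1 recovers the Fechner law g(r) = ln(1 - b r)/ln(1 - b) with

    b = K2^2 / (w_res^2 + K2^2) = 1 / (c^2 + 1),   c = w_res / K2,

K2 = 2 sqrt(2) K1 sigma.  Because K2 grows with the marginal sd while
w_res is fixed, c scales inversely with sigma, predicting how the bias
shifts between display conditions of different sd.  The log-width is in
turn read as the differential entropy of the bivariate gaussian,
H = ln(2 pi e sigma_x sigma_y sqrt(1 - r^2)): each JND then corresponds
to a fixed number of perceived bits I75, linking the Weber coefficient
to the bias via k = -I75 ln(1 - b).  All entropies are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .observer import perceived_magnitude

__all__ = [
    "TheoryParams",
    "K1_HALF_MAX",
    "bigauss_density",
    "isofraction_width",
    "magnitude_from_width",
    "bias_from_residual",
    "residual_from_bias",
    "predicted_bias_for_sigma",
    "differential_entropy",
    "ellipse_area",
    "unequal_sigma_magnitude",
    "unequal_sigma_jnd",
    "k_from_bits",
    "bits_from_k",
    "fechner_vs_entropy_rmse",
]

# half-maximum isofraction contour: density at the ellipse is half the peak
K1_HALF_MAX = math.sqrt(math.log(2.0))


@dataclass
class TheoryParams:
    """Constants of the entropy model.

    Only the composites b and c are empirically identified; K1, w_res
    and the ellipse-length surrogate are exposed for completeness but
    the bias is invariant to K1 at fixed c.
    """

    K1: float = K1_HALF_MAX
    sigma_x: float = 0.2
    sigma_y: float = 0.2
    w_res: float = 0.0
    n: int = 100

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("K1 and marginal sds must be positive")
        if self.w_res < 0:
            raise ValueError("w_res must be non-negative")

    @property
    def kappa(self) -> float:
        return self.sigma_y / self.sigma_x

    @property
    def K2(self) -> float:
        return 2.0 * math.sqrt(2.0) * self.K1 * self.sigma_x

    @property
    def c(self) -> float:
        return self.w_res / self.K2

    @property
    def b(self) -> float:
        return bias_from_residual(self.c)


def bigauss_density(
    x: float,
    y: float,
    mu_x: float = 0.0,
    mu_y: float = 0.0,
    sigma_x: float = 1.0,
    sigma_y: float = 1.0,
    r: float = 0.0,
):
    """Bivariate gaussian pdf f(x, y) = exp(-q) / (2 pi sx sy sqrt(1-r^2))."""
    if sigma_x <= 0 or sigma_y <= 0:
        raise ValueError("sds must be positive")
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be < 1 (degenerate otherwise)")
    dx = (np.asarray(x, dtype=float) - mu_x) / sigma_x
    dy = (np.asarray(y, dtype=float) - mu_y) / sigma_y
    q = (dx * dx - 2.0 * r * dx * dy + dy * dy) / (2.0 * (1.0 - r * r))
    out = np.exp(-q) / (2.0 * math.pi * sigma_x * sigma_y * math.sqrt(1.0 - r * r))
    return float(out) if out.ndim == 0 else out


def isofraction_width(
    r: float, sigma_x: float, kappa: float, K1: float = K1_HALF_MAX
) -> float:
    """Width (2 x semi-minor axis) of the isofraction ellipse q = K1^2.

    Closed form: 4 K1 sx sqrt(1-r^2) / sqrt((1 + 1/kappa^2) +
    sqrt((1 - 1/kappa^2)^2 + 4 r^2 / kappa^2)), with kappa = sy/sx.
    Reduces to 2 sqrt(2) K1 sigma sqrt(1-r) at kappa = 1, and to the
    sqrt(1-r^2) forms in the extreme-anisotropy limits.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    if sigma_x <= 0 or kappa <= 0 or K1 <= 0:
        raise ValueError("sigma_x, kappa, K1 must be positive")
    if r == 1.0:
        return 0.0
    ik2 = 1.0 / (kappa * kappa)
    denom = math.sqrt(
        (1.0 + ik2) + math.sqrt((1.0 - ik2) ** 2 + 4.0 * r * r * ik2)
    )
    return 4.0 * K1 * sigma_x * math.sqrt(1.0 - r * r) / denom


def magnitude_from_width(r, b: float):
    """Perceived magnitude via the width route (equal-sigma case).

    After normalizing g(0)=0, g(1)=1 the log-width model is identical to
    the Fechner law, so this simply evaluates it; a zero residual (b=1)
    is flagged as the divergent limit.
    """
    if b >= 1.0:
        raise ValueError("b = 1 (zero residual) gives a divergent law")
    return perceived_magnitude(r, b)


def bias_from_residual(c: float) -> float:
    """b = 1 / (c^2 + 1) for relative residual width c = w_res / K2."""
    if c < 0:
        raise ValueError("c must be non-negative")
    return 1.0 / (c * c + 1.0)


def residual_from_bias(b: float) -> float:
    """Inverse of :func:`bias_from_residual`: c = sqrt(1/b - 1)."""
    if not 0.0 < b <= 1.0:
        raise ValueError("b must lie in (0, 1]")
    return math.sqrt(1.0 / b - 1.0)


def predicted_bias_for_sigma(b_ref: float, sigma_ref: float, sigma_new: float) -> float:
    """Predict the bias at a new marginal sd from a calibrated reference.

    The residual width is fixed while K2 scales with sigma, so c is
    inversely proportional to sigma: c_new = c_ref * sigma_ref/sigma_new,
    b_new = 1/(c_new^2 + 1).
    """
    if sigma_ref <= 0 or sigma_new <= 0:
        raise ValueError("sds must be positive")
    c_new = residual_from_bias(b_ref) * (sigma_ref / sigma_new)
    return bias_from_residual(c_new)


def differential_entropy(
    sigma_x: float, sigma_y: float, r: float, n: int = 1
) -> float:
    """Differential entropy n ln(2 pi e sx sy sqrt(1 - r^2)), in nats."""
    if sigma_x <= 0 or sigma_y <= 0:
        raise ValueError("sds must be positive")
    if not -1.0 < r < 1.0:
        raise ValueError("entropy diverges to -inf as |r| -> 1")
    return n * math.log(
        2.0 * math.pi * math.e * sigma_x * sigma_y * math.sqrt(1.0 - r * r)
    )


def ellipse_area(
    r: float, sigma_x: float, sigma_y: float, K1: float = K1_HALF_MAX
) -> float:
    """Area of the isofraction ellipse: 2 pi sx sy K1^2 sqrt(1 - r^2).

    Satisfies the exact identity H(r) = n ln(A e / K1^2) with the
    differential entropy above.
    """
    if sigma_x <= 0 or sigma_y <= 0 or K1 <= 0:
        raise ValueError("sds and K1 must be positive")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    return 2.0 * math.pi * sigma_x * sigma_y * K1 * K1 * math.sqrt(1.0 - r * r)


def unequal_sigma_magnitude(r, b: float):
    """Exact-entropy magnitude law g(r) = ln(1 - b r^2) / ln(1 - b).

    This is the form the model takes when the ellipse area (hence the
    full sqrt(1 - r^2) dependence) drives perception, as in the
    markedly-unequal-sd limits.
    """
    if not 0.0 < b < 1.0:
        raise ValueError("b must lie in (0, 1)")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0.0) or np.any(r_arr > 1.0):
        raise ValueError("r must lie in [0, 1]")
    out = np.log1p(-b * r_arr * r_arr) / math.log1p(-b)
    return float(out) if out.ndim == 0 else out


def unequal_sigma_jnd(r: float, k_prime: float, b: float) -> float:
    """JND law paired with the exact-entropy magnitude: k' (1/(b r) - r)."""
    if not 0.0 < b < 1.0:
        raise ValueError("b must lie in (0, 1)")
    if r <= 0.0:
        raise ValueError("JND diverges at r = 0 under the r^2 law")
    if r > 1.0:
        raise ValueError("r must lie in (0, 1]")
    return k_prime * (1.0 / (b * r) - r)


def k_from_bits(I75: float, b: float) -> float:
    """Weber coefficient from the per-JND information: k = -I75 ln(1 - b)."""
    if I75 <= 0:
        raise ValueError("I75 must be positive")
    if not 0.0 <= b < 1.0:
        raise ValueError("b must lie in [0, 1)")
    return -I75 * math.log1p(-b)


def bits_from_k(k: float, b: float) -> float:
    """Perceived information per JND, in nats: I75 = -k / ln(1 - b)."""
    if not 0.0 < b < 1.0:
        raise ValueError("b must lie in (0, 1)")
    return -k / math.log1p(-b)


def fechner_vs_entropy_rmse(
    b_fechner: float, grid_n: int = 1001
) -> tuple[float, float]:
    """Best fit of the exact-entropy family to the Fechner curve.

    Evaluates g(r) = ln(1 - b r)/ln(1 - b) on a uniform ``grid_n``-point
    grid over [0, 1] and least-squares fits the one-parameter family
    ln(1 - b2 r^2)/ln(1 - b2) to it; returns (minimizing b2, RMSE
    between the curves).  The Fechner curve sits above the entropy fit
    at low correlations and below it at high ones.
    """
    if not 0.0 < b_fechner < 1.0:
        raise ValueError("b_fechner must lie in (0, 1)")
    r = np.linspace(0.0, 1.0, grid_n)
    target = perceived_magnitude(r, b_fechner)

    def rmse(b2: float) -> float:
        return float(
            np.sqrt(np.mean((unequal_sigma_magnitude(r, b2) - target) ** 2))
        )

    res = minimize_scalar(
        rmse, bounds=(1e-6, 1.0 - 1e-9), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(res.fun)
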