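"""Parametric simulated observer for correlation perception.

The observer perceives the correlation ``r`` of a scatterplot through a
logarithmic (Fechner) compression

    g(r) = ln(1 - b r) / ln(1 - b),        0 < b < 1,

with ``b`` the bias governing how strongly intermediate correlations are
underestimated (g(0)=0, g(1)=1, g convex).  Each look at a plot yields a
noisy internal magnitude g(r) + eps with eps ~ Normal(0, sigma_g^2): the
noise lives on the perceived-magnitude scale with constant sd, which is
the minimal model under which every just-noticeable difference spans the
same subjective increment.  Under that assumption the 75%-correct
discrimination threshold is exactly linear in (1/b - r), i.e. the
observer obeys Weber's law for the distance from r = 1 by construction,
with slope coefficient

    k = 1 - (1 - b)^(sqrt(2) * PhiInv(0.75) * sigma_g).

A two-alternative forced choice is modeled as two independent noisy
percepts, choosing the larger.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

__all__ = [
    "ObserverParams",
    "DELTA_G_UNIT",
    "perceived_magnitude",
    "percept",
    "discriminate",
    "theoretical_jnd",
    "weber_k",
    "sigma_for_weber_k",
]

# subjective-magnitude difference discriminated correctly 75% of the time
# per unit sigma_g in 2AFC: P(correct) = Phi(dg / (sigma_g * sqrt(2)))
DELTA_G_UNIT = math.sqrt(2.0) * norm.ppf(0.75)


@dataclass
class ObserverParams:
    """Bias and internal noise of a simulated observer.

    ``b``: bias in (0,1), the single free parameter of the perception
    laws.  ``sigma_g``: internal noise sd on the perceived-magnitude
    scale (dimensionless; 0 gives the noiseless limit).  ``seed`` is
    carried as metadata; all stochastic operations take an explicit rng.
    """

    b: float
    sigma_g: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.b < 1.0:
            raise ValueError(f"bias b must lie in (0, 1), got {self.b}")
        if self.sigma_g < 0.0:
            raise ValueError("sigma_g must be non-negative")
        # cached for the scalar fast path in percept()
        object.__setattr__(self, "_log1mb", math.log1p(-self.b))

    @property
    def k(self) -> float:
        """Implied Weber slope of the JND line in base-correlation space."""
        return weber_k(self)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps({"b": self.b, "sigma_g": self.sigma_g, "seed": self.seed})
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "ObserverParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))

    @classmethod
    def from_weber(
        cls, b: float, k: float, seed: int | None = None
    ) -> "ObserverParams":
        """Calibrate sigma_g so the observer's JND line has coefficient ``k``."""
        return cls(b=b, sigma_g=sigma_for_weber_k(k, b), seed=seed)


def perceived_magnitude(r, b: float):
    """Fechner law g(r) = ln(1 - b r) / ln(1 - b); accepts scalar or array r."""
    if not 0.0 < b < 1.0:
        raise ValueError(f"bias b must lie in (0, 1), got {b}")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0.0) or np.any(r_arr > 1.0):
        raise ValueError("correlation must lie in [0, 1]")
    out = np.log1p(-b * r_arr) / math.log1p(-b)
    return float(out) if np.isscalar(r) or r_arr.ndim == 0 else out


def percept(r: float, params: ObserverParams, rng: np.random.Generator) -> float:
    """One noisy look at a plot of correlation ``r`` (fresh noise per call)."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [0, 1]")
    g = math.log1p(-params.b * r) / params._log1mb  # scalar fast path
    if params.sigma_g == 0.0:
        return g
    return g + params.sigma_g * rng.standard_normal()


def discriminate(
    r1: float, r2: float, params: ObserverParams, rng: np.random.Generator
) -> int:
    """2AFC: return the index (0 or 1) of the plot judged more correlated.

    Each plot yields an independent noisy percept; ties (possible only in
    the noiseless limit) are broken at chance.
    """
    p1 = percept(r1, params, rng)
    p2 = percept(r2, params, rng)
    if p1 == p2:
        return int(rng.integers(2))
    return 0 if p1 > p2 else 1


def weber_k(params: ObserverParams) -> float:
    """Coefficient of the observer's JND-from-above line k(1/b - r)."""
    return 1.0 - (1.0 - params.b) ** (DELTA_G_UNIT * params.sigma_g)


def sigma_for_weber_k(k: float, b: float) -> float:
    """Internal noise sd that yields JND coefficient ``k`` at bias ``b``."""
    if not 0.0 < k < 1.0:
        raise ValueError("k must lie in (0, 1)")
    if not 0.0 < b < 1.0:
        raise ValueError("b must lie in (0, 1)")
    return math.log1p(-k) / (DELTA_G_UNIT * math.log1p(-b))


def theoretical_jnd(
    r: float,
    params: ObserverParams,
    direction: str = "above",
    check_range: bool = False,
) -> float:
    """Exact 75%-correct threshold Delta for this observer at base ``r``.

    Solves Phi(|g(r +/- D) - g(r)| / (sigma_g sqrt(2))) = 0.75 in closed
    form.  From above the threshold is k (1/b - r) with k = 1 -
    (1-b)^dg*; from below it is ((1-b)^-dg* - 1)(1/b - r) — both exactly
    linear in (1/b - r).  With ``check_range`` the function raises if the
    implied test correlation leaves [0, 1] (floor/ceiling signal).
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("base correlation must lie in [0, 1]")
    b = params.b
    dg = DELTA_G_UNIT * params.sigma_g
    u = 1.0 / b - r
    if direction == "above":
        delta = u * (1.0 - (1.0 - b) ** dg)
        if check_range and r + delta > 1.0:
            raise ValueError("threshold exceeds r = 1 (ceiling)")
    elif direction == "below":
        delta = u * ((1.0 - b) ** (-dg) - 1.0)
        if check_range and r - delta < 0.0:
            raise ValueError("threshold exceeds r = 0 (floor)")
    else:
        raise ValueError("direction must be 'above' or 'below'")
    return delta
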