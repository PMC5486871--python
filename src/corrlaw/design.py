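"""Scatterplot-design evaluation metrics and the reduced quick protocol.

Once a design's Weber parameters (k, b) are known, two scalar scores
summarize how well it conveys correlation, assuming every level of
correlation is equally likely:

* scatter ``S = k (1/b - 1/2)`` — the JND averaged over r in [0, 1]
  (precision; lower is better);
* error ``E = 1/b - 1/2 + 1/ln(1 - b)`` — the mean underestimation
  integral of r - g(r) over [0, 1] (accuracy; lower is better).

Both are exact integrals of the Weber and Fechner laws.  The quick
protocol estimates (k, b) from above-direction staircases at a reduced
set of base correlations (default {0.3, 0.6, 0.9}) — measurements at as
few as three bases recover the full-design estimates well, and no
bisection is needed because the two laws share the one bias parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lawfit import WeberFit, aggregate_jnds, apply_range_constraint, fit_weber_line
from .observer import ObserverParams
from .staircase import StaircaseConfig, StaircaseRun, run_condition

__all__ = ["DesignScore", "scatter_S", "error_E", "quick_evaluate",
           "QUICK_BASES"]

QUICK_BASES: tuple[float, ...] = (0.3, 0.6, 0.9)


@dataclass
class DesignScore:
    k: float
    b: float
    S: float
    E: float
    fit: WeberFit | None = None


def scatter_S(k: float, b: float) -> float:
    """Mean JND over r in [0,1]: S = k (1/b - 1/2)."""
    if not 0.0 < k < 1.0:
        raise ValueError("k must lie in (0, 1)")
    if not 0.0 < b <= 1.0:
        raise ValueError("b must lie in (0, 1]")
    return k * (1.0 / b - 0.5)


def error_E(b: float) -> float:
    """Mean underestimation over r in [0,1]: E = 1/b - 1/2 + 1/ln(1-b)."""
    if not 0.0 < b < 1.0:
        raise ValueError("b must lie in (0, 1)")
    return 1.0 / b - 0.5 + 1.0 / math.log1p(-b)


def quick_evaluate(
    observer: ObserverParams | None = None,
    jnd_runs: Sequence[StaircaseRun] | None = None,
    bases: Sequence[float] = QUICK_BASES,
    cfg: StaircaseConfig = StaircaseConfig(),
    n_observers: int = 1,
    rng: np.random.Generator | None = None,
) -> DesignScore:
    """Reduced-sampling design evaluation: (k, b, S, E) from a few bases.

    Either simulates above-direction staircases for ``observer`` at the
    given bases, or consumes pre-measured runs (e.g. a user JND table via
    :func:`corrlaw.lawfit.runs_from_jnd_table`).  Two bases are the
    minimal admissible design and trigger a warning.
    """
    if len(bases) < 2:
        raise ValueError("need at least 2 base correlations")
    if len(bases) == 2:
        warnings.warn(
            "2-base design: the Weber line is a line through two points; "
            "estimates may be fragile", stacklevel=2,
        )
    if jnd_runs is None:
        if observer is None:
            raise ValueError("provide either an observer or measured runs")
        jnd_runs = run_condition(
            sorted(bases), observer, cfg, n_observers=n_observers, rng=rng,
            below_min_base=math.inf,  # quick protocol: above only
        )
    points = apply_range_constraint(aggregate_jnds(jnd_runs))
    fit = fit_weber_line(points)
    return DesignScore(
        k=fit.k,
        b=fit.b_disc,
        S=scatter_S(fit.k, fit.b_disc),
        E=error_E(fit.b_disc),
        fit=fit,
    )
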