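"""Aggregation and law fitting for discrimination and estimation data.

The analysis pipeline mirrors standard practice for correlation-JND
experiments: per-cell JNDs are log-averaged across observers, plotted
against the adjusted correlation r_A = r +/- JND/2 (the mean of the two
plot correlations, which symmetrizes above- and below-direction runs),
screened by a range constraint (a cell is dropped when its test
correlation, mean +/- 2.5 sd across observers, crosses 0 or 1), and fit
by ordinary least squares:

    JND(r_A) = k (1/b_disc - r_A)

with variability ``k`` the negative slope and bias ``b_disc`` the
reciprocal of the r-axis intercept.  Bisection level estimates are fit
by the one-parameter Fechner law g(r) = ln(1 - b r)/ln(1 - b) via
bounded 1-D least squares.  Biases are averaged on the probit scale
(capped at 0.99) to tame their skew, and the discrimination/estimation
biases are compared by a paired t-test on that scale — the test of the
Fechner assumption that the two tasks measure one quantity b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .observer import perceived_magnitude
from .staircase import StaircaseRun

__all__ = [
    "JndPoint",
    "WeberFit",
    "FechnerFit",
    "BiasComparison",
    "PROBIT_CAP",
    "aggregate_jnds",
    "apply_range_constraint",
    "fit_weber_line",
    "fit_fechner",
    "probit_mean_bias",
    "compare_biases",
    "weber_slope_to_base_k",
    "base_k_to_weber_slope",
    "per_observer_weber",
    "per_observer_fechner",
    "jnd_table_from_runs",
    "runs_from_jnd_table",
]

PROBIT_CAP = 0.99


@dataclass
class JndPoint:
    """One (base, direction) cell aggregated across observers."""

    base_r: float
    direction: str
    jnd: float            # geometric mean across observers
    adjusted_r: float     # r_A = base +/- jnd/2
    test_mean: float      # arithmetic mean of per-observer test correlations
    test_sd: float        # sd (ddof=1) of per-observer test correlations
    n_observers: int


@dataclass
class WeberFit:
    k: float
    b_disc: float
    y_intercept: float
    r_squared: float
    ci_k: tuple[float, float]
    ci_b: tuple[float, float]
    n_points: int


@dataclass
class FechnerFit:
    b_est: float
    rmse: float


@dataclass
class BiasComparison:
    t_stat: float
    p_value: float
    mean_difference: float
    n: int


def _signed_test_corr(base_r: float, direction: str, jnd: float) -> float:
    return base_r + jnd if direction == "above" else base_r - jnd


def aggregate_jnds(runs: Iterable[StaircaseRun]) -> list[JndPoint]:
    """Geometric-mean JND per (base, direction) cell with adjusted correlation.

    JNDs are log-transformed before averaging across observers; the
    adjusted correlation uses the signed convention r_A = base + jnd/2
    from above and base - jnd/2 from below.
    """
    cells: dict[tuple[float, str], list[float]] = {}
    for run in runs:
        cells.setdefault((run.base_r, run.direction), []).append(run.jnd)
    if not cells:
        raise ValueError("no runs to aggregate")
    points = []
    for (base, direction), jnds in sorted(cells.items()):
        if any(j <= 0 for j in jnds):
            raise ValueError("JNDs must be positive for log-averaging")
        gm = math.exp(float(np.mean(np.log(jnds))))
        sign = 0.5 if direction == "above" else -0.5
        tests = [_signed_test_corr(base, direction, j) for j in jnds]
        points.append(
            JndPoint(
                base_r=base,
                direction=direction,
                jnd=gm,
                adjusted_r=base + sign * gm,
                test_mean=float(np.mean(tests)),
                test_sd=float(np.std(tests, ddof=1)) if len(tests) > 1 else 0.0,
                n_observers=len(jnds),
            )
        )
    return points


def apply_range_constraint(
    points: Sequence[JndPoint], n_sd: float = 2.5
) -> list[JndPoint]:
    """Drop cells whose test correlation, mean +/- ``n_sd`` sd, leaves [0, 1]."""
    kept = []
    for p in points:
        lo = p.test_mean - n_sd * p.test_sd
        hi = p.test_mean + n_sd * p.test_sd
        if lo >= 0.0 and hi <= 1.0:
            kept.append(p)
    return kept


def fit_weber_line(points: Sequence[JndPoint]) -> WeberFit:
    """OLS of JND on adjusted correlation; k = -slope, b = -slope/intercept.

    95% CIs: Student-t for the slope; first-order delta method for the
    bias (a ratio of the two coefficients).  The bias is capped at 0.99,
    matching the probit cap applied downstream.
    """
    x = np.array([p.adjusted_r for p in points], dtype=float)
    y = np.array([p.jnd for p in points], dtype=float)
    if x.size < 2 or np.ptp(x) == 0.0:
        raise ValueError("need >= 2 points with distinct adjusted correlations")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept, slope = float(beta[0]), float(beta[1])
    resid = y - X @ beta
    dof = x.size - 2
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    k = -slope
    if intercept <= 0.0:
        raise ValueError("non-positive y-intercept: Weber bias undefined")
    b_disc = min(k / intercept, PROBIT_CAP)

    if dof > 0:
        sigma2 = ss_res / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        tval = stats.t.ppf(0.975, dof)
        se_k = math.sqrt(cov[1, 1])
        # b = -slope/intercept: gradient wrt (intercept, slope)
        grad = np.array([slope / intercept**2, -1.0 / intercept])
        se_b = math.sqrt(float(grad @ cov @ grad))
        ci_k = (k - tval * se_k, k + tval * se_k)
        ci_b = (b_disc - tval * se_b, b_disc + tval * se_b)
    else:
        ci_k = (math.nan, math.nan)
        ci_b = (math.nan, math.nan)

    return WeberFit(
        k=k,
        b_disc=b_disc,
        y_intercept=intercept,
        r_squared=r_squared,
        ci_k=ci_k,
        ci_b=ci_b,
        n_points=x.size,
    )


def weber_slope_to_base_k(k_fit: float) -> float:
    """Convert the r_A-space JND slope to the base-correlation-space coefficient.

    A threshold Delta = k0 (1/b - r) measured at base r plots at
    r_A = r + Delta/2, giving an exactly linear line in r_A with slope
    magnitude k0 / (1 - k0/2) (identically from below); this inverts
    that mapping: k0 = k_fit / (1 + k_fit/2).
    """
    return k_fit / (1.0 + k_fit / 2.0)


def base_k_to_weber_slope(k0: float) -> float:
    """Inverse of :func:`weber_slope_to_base_k`."""
    return k0 / (1.0 - k0 / 2.0)


def fit_fechner(
    level_estimates: dict[float, float] | Sequence[tuple[float, float]],
    b_max: float = PROBIT_CAP,
    grid_step: float = 1e-4,
) -> FechnerFit:
    """Bounded 1-D least squares of the Fechner law to (level, r) pairs.

    Minimizes sum (g(r_i; b) - level_i)^2 over b in (0, ``b_max``] by a
    dense grid at ``grid_step`` resolution refined with bounded local
    search; returns the minimizing bias and the RMSE of the fit.
    """
    if isinstance(level_estimates, dict):
        pairs = sorted(level_estimates.items())
    else:
        pairs = sorted(level_estimates)
    if len(pairs) < 2:
        raise ValueError("need at least 2 (level, r) pairs")
    levels = np.array([p[0] for p in pairs], dtype=float)
    rs = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(rs) == 0.0:
        raise ValueError("all estimates identical: bias not identifiable")

    bs = np.arange(grid_step, b_max + grid_step / 2, grid_step)
    g = np.log1p(-np.outer(bs, rs)) / np.log1p(-bs)[:, None]
    sse = ((g - levels) ** 2).sum(axis=1)
    i = int(np.argmin(sse))

    lo = bs[max(i - 1, 0)]
    hi = min(bs[min(i + 1, bs.size - 1)], b_max)
    def sse_at(b: float) -> float:
        return float(((perceived_magnitude(rs, b) - levels) ** 2).sum())
    res = minimize_scalar(sse_at, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-9})
    b_best, best = (float(res.x), float(res.fun))
    if sse[i] < best:  # guard: boundary minimum
        b_best, best = float(bs[i]), float(sse[i])
    return FechnerFit(b_est=b_best, rmse=math.sqrt(best / levels.size))


def probit_mean_bias(
    biases: Sequence[float], cap: float = PROBIT_CAP
) -> tuple[float, tuple[float, float]]:
    """Mean bias and 95% CI computed on the probit scale, back-transformed.

    Each bias must lie in (0, 1); values above ``cap`` are capped before
    the inverse-normal transform.
    """
    b = np.asarray(biases, dtype=float)
    if np.any(b <= 0.0) or np.any(b >= 1.0):
        raise ValueError("biases must lie in (0, 1)")
    z = stats.norm.ppf(np.minimum(b, cap))
    m = float(z.mean())
    if z.size > 1 and z.std(ddof=1) > 0:
        half = stats.t.ppf(0.975, z.size - 1) * z.std(ddof=1) / math.sqrt(z.size)
        ci = (float(stats.norm.cdf(m - half)), float(stats.norm.cdf(m + half)))
    else:
        ci = (math.nan, math.nan)
    return float(stats.norm.cdf(m)), ci


def compare_biases(
    b_disc: Sequence[float], b_est: Sequence[float], cap: float = PROBIT_CAP
) -> BiasComparison:
    """Paired two-tailed t-test of discrimination vs estimation biases.

    The test statistic is computed on probit-transformed (capped) biases;
    the reported effect is the mean raw difference.
    """
    bd = np.asarray(b_disc, dtype=float)
    be = np.asarray(b_est, dtype=float)
    if bd.shape != be.shape:
        raise ValueError("paired samples must have equal length")
    zd = stats.norm.ppf(np.minimum(bd, cap))
    ze = stats.norm.ppf(np.minimum(be, cap))
    if np.allclose(zd, ze):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(zd, ze)
    return BiasComparison(
        t_stat=float(t_stat),
        p_value=float(p),
        mean_difference=float(np.mean(bd - be)),
        n=bd.size,
    )


def per_observer_weber(
    runs: Iterable[StaircaseRun],
    cells: Sequence[tuple[float, str]] | None = None,
    skip_failures: bool = False,
) -> dict[int, WeberFit]:
    """Weber fit per observer, optionally restricted to surviving cells.

    With ``skip_failures`` observers whose individual fit is inadmissible
    (non-positive intercept or slope, possible in very noisy cohorts) are
    silently dropped instead of raising.
    """
    by_obs: dict[int, list[StaircaseRun]] = {}
    for run in runs:
        if cells is not None and (run.base_r, run.direction) not in cells:
            continue
        by_obs.setdefault(run.observer_id, []).append(run)
    fits: dict[int, WeberFit] = {}
    for obs, obs_runs in sorted(by_obs.items()):
        try:
            fit = fit_weber_line(aggregate_jnds(obs_runs))
        except ValueError:
            if skip_failures:
                continue
            raise
        if skip_failures and not (0.0 < fit.b_disc and 0.0 < fit.k < 1.0):
            continue
        fits[obs] = fit
    return fits


def outlier_observer_ids(
    values: dict[int, float], n_sd: float = 2.5
) -> set[int]:
    """Observers whose value lies > ``n_sd`` sds beyond the average of the others.

    Leave-one-out version of the cohort screening rule used when
    recruiting human observers (flagged observers were replaced there;
    simulated cohorts simply exclude them from summary statistics).
    """
    if len(values) < 3:
        return set()
    ids = list(values)
    arr = np.array([values[i] for i in ids], dtype=float)
    flagged = set()
    for j, obs in enumerate(ids):
        others = np.delete(arr, j)
        sd = others.std(ddof=1)
        if sd > 0 and abs(arr[j] - others.mean()) > n_sd * sd:
            flagged.add(obs)
    return flagged


def per_observer_fechner(
    protocols: dict[int, dict[float, float]]
) -> dict[int, FechnerFit]:
    """Fechner fit per observer from each observer's level estimates."""
    return {obs: fit_fechner(est) for obs, est in sorted(protocols.items())}


def jnd_table_from_runs(runs: Iterable[StaircaseRun]) -> pd.DataFrame:
    """Tidy per-run JND table (observer, base_r, direction, jnd, converged)."""
    return pd.DataFrame(
        [
            {
                "observer": r.observer_id,
                "base_r": r.base_r,
                "direction": r.direction,
                "jnd": r.jnd,
                "converged": r.converged,
            }
            for r in runs
        ]
    )


def runs_from_jnd_table(table: pd.DataFrame) -> list[StaircaseRun]:
    """Rebuild minimal run records from a JND table (e.g. user-supplied CSV)."""
    runs = []
    for row in table.itertuples(index=False):
        runs.append(
            StaircaseRun(
                base_r=float(row.base_r),
                direction=str(row.direction),
                trials=[],
                jnd=float(row.jnd),
                converged=bool(getattr(row, "converged", True)),
                n_trials=0,
                observer_id=int(getattr(row, "observer", 0)),
            )
        )
    return runs
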