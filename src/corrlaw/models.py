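"""Candidate magnitude-law comparison: fit g(r) families and rank by RMSE.

Each candidate maps physical correlation r in [0, 1] to a perceived
magnitude with g(0) = 0 and g(1) = 1 (after normalization).  Families
are identified by the letters conventional in the correlation-perception
literature; only rows whose functional form is fully determined are
built in — the remainder must be supplied explicitly (e.g. from a YAML
config) rather than guessed, since their constants live in the original
sources.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "ModelSpec",
    "REGISTRY",
    "UNIMPLEMENTED",
    "register_model",
    "load_models_config",
    "evaluate_model",
    "fit_model",
    "model_table",
]


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    description: str
    n_free_params: int
    func: Callable[..., np.ndarray]      # func(r, *params)
    bounds: tuple[tuple[float, float], ...] = ()


def _axis_ratio(r: np.ndarray) -> np.ndarray:
    """Minor/major axis ratio of the equal-sd iso-density ellipse."""
    return np.sqrt((1.0 - r) / (1.0 + r))


def _fechner(r: np.ndarray, b: float) -> np.ndarray:
    return np.log1p(-b * r) / math.log1p(-b)


REGISTRY: dict[str, ModelSpec] = {}

UNIMPLEMENTED: dict[str, str] = {
    letter: "formula defined only in cited source; supply via config"
    for letter in ("B", "C", "D", "E", "F", "G", "L", "N", "P")
}


def register_model(spec: ModelSpec) -> None:
    REGISTRY[spec.model_id] = spec


register_model(ModelSpec(
    "A", "variance: g = r^2", 0,
    lambda r: r * r,
))
register_model(ModelSpec(
    "H", "power of distance from r=1: g = 1 - (1-r)^a", 1,
    lambda r, a: 1.0 - (1.0 - r) ** a,
    bounds=((0.05, 5.0),),
))
register_model(ModelSpec(
    "I", "power of iso-density axis ratio: g = 1 - ((1-r)/(1+r))^(a/2)", 1,
    lambda r, a: 1.0 - _axis_ratio(np.asarray(r, dtype=float)) ** a,
    bounds=((0.05, 5.0),),
))
register_model(ModelSpec(
    "J", "Fechner law: g = ln(1-br)/ln(1-b)", 1,
    _fechner,
    bounds=((1e-4, 0.99),),
))
register_model(ModelSpec(
    "K", "entropy of the true ellipse area: g = ln(1-br^2)/ln(1-b)", 1,
    lambda r, b: np.log1p(-b * np.asarray(r, dtype=float) ** 2) / math.log1p(-b),
    bounds=((1e-4, 0.99),),
))
register_model(ModelSpec(
    "M", "two-parameter power of distance from r=1: g = (1-(1-r)^c)^a", 2,
    lambda r, a, c: (1.0 - (1.0 - r) ** c) ** a,
    bounds=((0.05, 5.0), (0.05, 5.0)),
))
register_model(ModelSpec(
    "O", "power law for u = 1-br: g = (1-(1-br)^a)/(1-(1-b)^a)", 2,
    lambda r, a, b: (1.0 - (1.0 - b * r) ** a) / (1.0 - (1.0 - b) ** a),
    bounds=((0.02, 3.0), (1e-4, 0.9999)),
))


def _get_spec(model_id: str) -> ModelSpec:
    if model_id in REGISTRY:
        return REGISTRY[model_id]
    if model_id in UNIMPLEMENTED:
        raise NotImplementedError(f"model {model_id}: {UNIMPLEMENTED[model_id]}")
    raise KeyError(f"unknown model id {model_id!r}")


def evaluate_model(model_id: str, params: Sequence[float], r):
    """Evaluate family ``model_id`` at ``r`` with the given parameters."""
    spec = _get_spec(model_id)
    params = tuple(params)
    if len(params) != spec.n_free_params:
        raise ValueError(
            f"model {model_id} takes {spec.n_free_params} parameters, "
            f"got {len(params)}"
        )
    for value, (lo, hi) in zip(params, spec.bounds):
        if not lo <= value <= hi:
            raise ValueError(f"parameter {value} outside bounds [{lo}, {hi}]")
    r_arr = np.asarray(r, dtype=float)
    out = np.asarray(spec.func(r_arr, *params), dtype=float)
    return float(out) if out.ndim == 0 else out


def _rmse(spec: ModelSpec, params: Sequence[float],
          rs: np.ndarray, levels: np.ndarray) -> float:
    with np.errstate(all="ignore"):
        g = np.asarray(spec.func(rs, *params), dtype=float)
    if not np.all(np.isfinite(g)):
        return math.inf
    return float(np.sqrt(np.mean((g - levels) ** 2)))


def fit_model(
    model_id: str,
    level_estimates: dict[float, float] | Sequence[tuple[float, float]],
    grid_points: int = 400,
) -> tuple[tuple[float, ...], float]:
    """Least-squares fit of one family to (level, r) pairs -> (params, rmse).

    Bounded dense grid search refined by local optimization; 0-parameter
    families are evaluated directly.
    """
    spec = _get_spec(model_id)
    if isinstance(level_estimates, dict):
        pairs = sorted(level_estimates.items())
    else:
        pairs = sorted(level_estimates)
    if len(pairs) < spec.n_free_params + 1:
        raise ValueError("need more data points than free parameters")
    levels = np.array([p[0] for p in pairs], dtype=float)
    rs = np.array([p[1] for p in pairs], dtype=float)

    if spec.n_free_params == 0:
        return (), _rmse(spec, (), rs, levels)

    if spec.n_free_params == 1:
        (lo, hi), = spec.bounds
        grid = np.linspace(lo, hi, grid_points)
        errs = [_rmse(spec, (g,), rs, levels) for g in grid]
        i = int(np.argmin(errs))
        res = minimize_scalar(
            lambda p: _rmse(spec, (p,), rs, levels),
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, grid_points - 1)]),
            method="bounded", options={"xatol": 1e-9},
        )
        if res.fun <= errs[i]:
            return (float(res.x),), float(res.fun)
        return (float(grid[i]),), float(errs[i])

    # >= 2 parameters: coarse product grid, then Nelder-Mead clipped to bounds
    axes = [np.linspace(lo, hi, 40) for lo, hi in spec.bounds]
    best_p, best_e = None, math.inf
    for combo in itertools.product(*axes):
        e = _rmse(spec, combo, rs, levels)
        if e < best_e:
            best_p, best_e = combo, e

    def clipped(p: np.ndarray) -> tuple[float, ...]:
        return tuple(
            min(max(v, lo), hi) for v, (lo, hi) in zip(p, spec.bounds)
        )

    res = minimize(
        lambda p: _rmse(spec, clipped(p), rs, levels),
        x0=np.asarray(best_p), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
    )
    cand = clipped(res.x)
    cand_e = _rmse(spec, cand, rs, levels)
    if cand_e <= best_e:
        return cand, cand_e
    return tuple(map(float, best_p)), best_e


def model_table(
    level_estimates: dict[float, float] | Sequence[tuple[float, float]],
    model_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fit every requested family and rank by RMSE within parameter strata."""
    if model_ids is None:
        model_ids = sorted(REGISTRY)
    rows = []
    for mid in model_ids:
        spec = _get_spec(mid)
        params, rmse = fit_model(mid, level_estimates)
        rows.append(
            {
                "model": mid,
                "description": spec.description,
                "n_params": spec.n_free_params,
                "params": params,
                "rmse": rmse,
            }
        )
    df = pd.DataFrame(rows, columns=["model", "description", "n_params",
                                     "params", "rmse"])
    return df.sort_values(["n_params", "rmse"], kind="stable").reset_index(drop=True)


def load_models_config(path: str | Path) -> list[str]:
    """Register user-defined magnitude laws from a YAML config.

    Schema per entry::

        B:
          description: my law
          expression: "1 - (1 - r)**a"   # sympy syntax, variable r
          params: [a]
          bounds: [[0.1, 4.0]]

    Returns the list of registered model ids.
    """
    import sympy

    config = yaml.safe_load(Path(path).read_text())
    registered = []
    for model_id, entry in config.items():
        param_names = list(entry.get("params", []))
        symbols = sympy.symbols(["r"] + param_names)
        expr = sympy.sympify(entry["expression"])
        func = sympy.lambdify(symbols, expr, modules="numpy")
        bounds = tuple(tuple(map(float, bd)) for bd in entry.get("bounds", []))
        if len(bounds) != len(param_names):
            raise ValueError(f"model {model_id}: bounds/params length mismatch")
        register_model(
            ModelSpec(
                model_id=str(model_id),
                description=str(entry.get("description", entry["expression"])),
                n_free_params=len(param_names),
                func=func,
                bounds=bounds,
            )
        )
        registered.append(str(model_id))
    return registered
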