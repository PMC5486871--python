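"""Synthesis of scatterplot dot clouds at a target Pearson correlation.

Two generators are provided, matching the two stimulus classes used in
correlation-perception experiments:

* **Gaussian clouds** — independent normal marginals mixed by a linear
  transform that imposes the target correlation, with outlier replacement
  (any point beyond 2.5 sd of the mean is redrawn), a correlation
  adjustment step that brings the realized sample correlation within a
  tolerance (default 0.005) of the target, and a final rescaling to the
  configured mean and standard deviation.

* **Uniform clouds** — a sorted list of uniform x-draws paired with a
  scrambled copy of itself, partially re-ordered by a comb sort that is
  halted as soon as the sample correlation reaches the target.

Coordinates live in abstract "cloud units" (nominally mean 0.5, sd 0.2 of
the cloud extent); rendering to pixels is out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DotCloud",
    "lambda_for_r",
    "apply_correlation_transform",
    "make_gaussian_cloud",
    "comb_sort_to_correlation",
    "make_uniform_cloud",
]

DEFAULT_TOL = 0.005
CLIP_SD = 2.5


@dataclass
class DotCloud:
    """A synthesized scatterplot: point coordinates plus generation metadata.

    ``sd_x`` and ``sd_y`` are the marginal standard deviations actually
    imposed on the displayed cloud (population convention, ddof=0);
    ``aspect_ratio`` is sigma_y / sigma_x.
    """

    xs: np.ndarray
    ys: np.ndarray
    n: int
    target_r: float
    realized_r: float
    distribution: str
    mean: float
    sd_x: float
    sd_y: float
    aspect_ratio: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        """Write coordinates as a two-column CSV plus a JSON metadata sidecar."""
        path = Path(path)
        arr = np.column_stack([self.xs, self.ys])
        header = "x,y"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = {
            "n": self.n,
            "target_r": self.target_r,
            "realized_r": self.realized_r,
            "distribution": self.distribution,
            "mean": self.mean,
            "sd_x": self.sd_x,
            "sd_y": self.sd_y,
            "aspect_ratio": self.aspect_ratio,
            "seed": self.seed,
        }
        sidecar.write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DotCloud":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(xs=arr[:, 0], ys=arr[:, 1], **meta)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(xc @ yc) / denom


def _standardize(a: np.ndarray) -> np.ndarray:
    """Zero mean, unit population (ddof=0) standard deviation."""
    a = np.asarray(a, dtype=float)
    sd = a.std()
    if sd == 0.0:
        raise ValueError("zero-variance input cannot be standardized")
    return (a - a.mean()) / sd


def lambda_for_r(r: float) -> float:
    """Mixing weight lambda that imposes population correlation ``r``.

    The transform ``y' = (lx + (1-l)y) / sqrt(l^2 + (1-l)^2)`` applied to
    independent unit-variance sequences has corr(y', x) = l / sqrt(l^2 +
    (1-l)^2).  Solving for l gives the closed form ``l = r / (r +
    sqrt(1 - r^2))``, which is algebraically equivalent to the textbook
    form ``(r^2 - sqrt(r^2 - r^4)) / (2 r^2 - 1)`` but has no removable
    singularity at 2 r^2 = 1.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [0, 1], got {r}")
    if r == 1.0:
        return 1.0
    return r / (r + math.sqrt(1.0 - r * r))


def apply_correlation_transform(
    xs: np.ndarray, ys: np.ndarray, r: float
) -> np.ndarray:
    """Mix two standardized sequences so the output correlates with ``xs`` at ``r``.

    Both inputs must be standardized (zero mean, unit variance).  The
    output has unit variance and expected correlation ``r`` with ``xs``.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("xs and ys must have the same length")
    if xs.std() == 0.0 or ys.std() == 0.0:
        raise ValueError("zero-variance input")
    lam = lambda_for_r(r)
    if lam == 0.0:
        return ys.copy()
    if lam == 1.0:
        return xs.copy()
    return (lam * xs + (1.0 - lam) * ys) / math.sqrt(
        lam * lam + (1.0 - lam) * (1.0 - lam)
    )


def _impose_exact_correlation(x: np.ndarray, y: np.ndarray, r: float) -> np.ndarray:
    """Residual orthogonalization: return y* with sample corr(x, y*) exactly r.

    Regresses y on x, standardizes the (sample-orthogonal) residual and
    recombines as ``r*x + sqrt(1-r^2)*e``; preserves marginal shape closely.
    """
    x = _standardize(x)
    y = _standardize(y)
    rho = float(np.mean(x * y))
    e = y - rho * x
    if e.std() == 0.0:
        # y already perfectly collinear with x
        if r == 1.0:
            return x
        raise ValueError("degenerate residual: cannot impose correlation < 1")
    e = _standardize(e)
    return r * x + math.sqrt(max(0.0, 1.0 - r * r)) * e


def make_gaussian_cloud(
    n: int,
    target_r: float,
    mean: float = 0.5,
    sd: float = 0.2,
    aspect_ratio: float = 1.0,
    tol: float = DEFAULT_TOL,
    rng: np.random.Generator | None = None,
    max_attempts: int = 50,
) -> DotCloud:
    """Generate a gaussian dot cloud whose sample correlation hits ``target_r``.

    Pipeline: sample two independent normal sequences, standardize,
    mix them to the target correlation, replace any point farther than
    2.5 sd from the mean with a fresh draw, adjust the realized sample
    correlation to within ``tol`` of the target (exact residual
    orthogonalization when out of tolerance), then rescale each dimension
    to the configured mean and standard deviation.  ``aspect_ratio`` =
    sigma_y / sigma_x compresses x (e.g. 2.0 halves the horizontal sd).

    Raises ``RuntimeError`` if no admissible cloud is found within
    ``max_attempts`` regenerations.
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    if not 0.0 <= target_r <= 1.0:
        raise ValueError("target_r must lie in [0, 1]")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if sd <= 0 or aspect_ratio <= 0:
        raise ValueError("sd and aspect_ratio must be positive")
    rng = np.random.default_rng() if rng is None else rng

    for _ in range(max_attempts):
        x = _standardize(rng.standard_normal(n))
        y = _standardize(rng.standard_normal(n))
        yt = apply_correlation_transform(x, y, target_r)

        # replace out-of-range points with fresh draws (bounded loop)
        ok = False
        for _ in range(100):
            bad = (np.abs(x) > CLIP_SD) | (np.abs(yt) > CLIP_SD)
            if not bad.any():
                ok = True
                break
            m = int(bad.sum())
            xn = rng.standard_normal(m)
            yn = rng.standard_normal(m)
            lam = lambda_for_r(target_r)
            denom = math.sqrt(lam * lam + (1.0 - lam) * (1.0 - lam))
            x[bad] = xn
            yt[bad] = (lam * xn + (1.0 - lam) * yn) / denom
        if not ok:
            continue

        xf = _standardize(x)
        if target_r == 1.0:
            yf = xf
            realized = 1.0
        else:
            if abs(_pearson(x, yt) - target_r) > tol:
                yt = _impose_exact_correlation(x, yt, target_r)
            yf = _standardize(yt)
            realized = _pearson(xf, yf)
        # re-standardization (and the adjustment) can nudge a borderline
        # point past the clip bound; the bound holds on the final coordinates
        if (np.abs(xf) > CLIP_SD).any() or (np.abs(yf) > CLIP_SD).any():
            continue

        sd_x = sd / aspect_ratio
        sd_y = sd
        xs = mean + sd_x * xf
        ys = mean + sd_y * yf
        return DotCloud(
            xs=xs,
            ys=ys,
            n=n,
            target_r=target_r,
            realized_r=realized,
            distribution="gaussian",
            mean=mean,
            sd_x=sd_x,
            sd_y=sd_y,
            aspect_ratio=aspect_ratio,
        )
    raise RuntimeError(
        f"failed to generate admissible gaussian cloud after {max_attempts} attempts"
    )


def comb_sort_to_correlation(
    xs: np.ndarray,
    ys: np.ndarray,
    target_r: float,
    tol: float = DEFAULT_TOL,
    shrink: float = 1.3,
    swap_trace: list | None = None,
) -> np.ndarray:
    """Partially comb-sort ``ys`` until corr(xs, ys) is within ``tol`` of target.

    If ``swap_trace`` is a list, the sample correlation after every
    executed swap is appended to it (diagnostic hook).

    ``xs`` must be sorted ascending and ``ys`` must be a permutation of
    ``xs`` (a scrambled copy); each executed swap then cannot decrease the
    sample correlation, so the sort sweeps the correlation monotonically
    upward and is halted at the first state inside the tolerance band.
    A full sort yields ys == xs and correlation exactly 1.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float).copy()
    n = xs.size
    if ys.size != n:
        raise ValueError("xs and ys must have the same length")
    if not 0.0 <= target_r <= 1.0:
        raise ValueError("target_r must lie in [0, 1]")
    if np.any(np.diff(xs) < 0):
        raise ValueError("xs must be sorted ascending")
    if not np.array_equal(np.sort(ys), xs):
        raise ValueError("ys must be a permutation of xs")

    mx = xs.mean()
    sx = xs.std()
    if sx == 0.0:
        raise ValueError("zero-variance input")
    # ys is a permutation of xs: identical mean and sd
    sxy = float(np.sum((xs - mx) * (ys - mx)))
    denom = n * sx * sx

    def corr() -> float:
        return sxy / denom

    if abs(corr() - target_r) <= tol:
        return ys

    gap = n
    while True:
        gap = max(1, int(gap / shrink))
        swapped = False
        for i in range(n - gap):
            j = i + gap
            if ys[i] > ys[j]:
                sxy += (xs[j] - xs[i]) * (ys[i] - ys[j])
                ys[i], ys[j] = ys[j], ys[i]
                swapped = True
                if swap_trace is not None:
                    swap_trace.append(corr())
                if abs(corr() - target_r) <= tol:
                    return ys
        if gap == 1 and not swapped:
            break
    raise RuntimeError(
        "comb sort finished without entering the tolerance band "
        f"(final correlation {corr():.4f}, target {target_r})"
    )


def make_uniform_cloud(
    n: int,
    target_r: float,
    mean: float = 0.5,
    value_range: float = 1.0,
    tol: float = DEFAULT_TOL,
    rng: np.random.Generator | None = None,
    max_attempts: int = 50,
) -> DotCloud:
    """Generate a uniform-marginal cloud via the scramble-and-comb-sort recipe.

    x-coordinates are uniform draws over ``mean +/- value_range/2``,
    rescaled to the exact mean and the uniform sd ``value_range/sqrt(12)``;
    y-coordinates are a scrambled copy, partially re-ordered by a comb
    sort until the sample correlation is within ``tol`` of the target.
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    if not 0.0 <= target_r <= 1.0:
        raise ValueError("target_r must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    sd = value_range / math.sqrt(12.0)

    for _ in range(max_attempts):
        xs = rng.uniform(mean - value_range / 2.0, mean + value_range / 2.0, n)
        xs.sort()
        xs = mean + sd * _standardize(xs)
        ys0 = rng.permutation(xs)
        r0 = _pearson(xs, ys0)
        if abs(r0 - target_r) > tol and r0 > target_r:
            # sorting only raises the correlation; need to start below the band
            continue
        try:
            ys = comb_sort_to_correlation(xs, ys0, target_r, tol=tol)
        except RuntimeError:
            continue
        return DotCloud(
            xs=xs,
            ys=ys,
            n=n,
            target_r=target_r,
            realized_r=_pearson(xs, ys),
            distribution="uniform",
            mean=mean,
            sd_x=sd,
            sd_y=sd,
            aspect_ratio=1.0,
        )
    raise RuntimeError(
        f"failed to generate admissible uniform cloud after {max_attempts} attempts"
    )
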