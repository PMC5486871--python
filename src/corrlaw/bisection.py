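"""Recursive bisection protocol for perceived-correlation magnitude.

The observer adjusts a test plot until its correlation appears halfway
between two reference plots.  Applied recursively — first between r = 0
and r = 1, then between each new estimate and its neighbours — the
protocol maps out the physical correlations corresponding to perceived
magnitudes g = 1/8, 1/4, ..., 7/8.

For a Fechner observer with bias ``b`` the noiseless perceptual midpoint
of references (lo, hi) has the closed form

    r* = (1 - sqrt((1 - b lo)(1 - b hi))) / b,

i.e. g(r*) = (g(lo) + g(hi)) / 2 exactly.  The human "adjust until
satisfied" loop is replaced by a reversal-counting policy: each
adjustment compares a fresh noisy percept of the test with the mean of
fresh noisy percepts of the references and steps toward the perceived
midpoint with a random step size in (0, (hi - lo)/10]; the rep stops
after a fixed number of direction reversals (or an adjustment cap) and
returns the mean test correlation over the last few reversals.  The
scientific content is the fixed point of this policy, not its path.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .observer import ObserverParams, percept

__all__ = [
    "BisectionConfig",
    "BisectionProtocolResult",
    "LEVELS",
    "midpoint_r",
    "noiseless_levels",
    "run_bisection_rep",
    "run_protocol",
]

LEVELS: tuple[float, ...] = (0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875)


@dataclass(frozen=True)
class BisectionConfig:
    """Adjustment-policy surrogate for the human "adjust until satisfied" loop.

    ``policy='time_average'`` (default) runs a fixed-length adjustment walk
    and returns the mean test position after a burn-in — a consistent
    estimator of the perceived midpoint at any noise level.
    ``policy='reversal'`` stops after ``max_reversals`` direction reversals
    and averages the last ``reversal_tail`` reversal values; cheaper, but
    it stops near the starting point when internal noise is large, so its
    estimates are pulled toward the references.
    """

    reps_per_level: int = 4
    start_offset: float = 0.1
    step_frac: float = 0.1        # max step as a fraction of (hi - lo)
    policy: str = "time_average"
    max_adjustments: int = 160
    burn_in: int = 40
    max_reversals: int = 6
    reversal_tail: int = 4        # reversals averaged for the estimate

    def __post_init__(self) -> None:
        if self.policy not in ("time_average", "reversal"):
            raise ValueError("policy must be 'time_average' or 'reversal'")
        if not 0 <= self.burn_in < self.max_adjustments:
            raise ValueError("burn_in must lie within the adjustment budget")


@dataclass
class BisectionProtocolResult:
    """Estimated physical correlations for the seven g = i/8 levels."""

    estimates: dict[float, float]
    reps: dict[float, list[float]] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["level", "rep", "estimate"])
            for level in sorted(self.reps):
                for i, est in enumerate(self.reps[level]):
                    writer.writerow([level, i, f"{est:.6f}"])


def midpoint_r(lo: float, hi: float, b: float) -> float:
    """Noiseless perceptual midpoint of two reference correlations.

    Solves g(r*) = (g(lo) + g(hi)) / 2 for the Fechner law with bias
    ``b``; evaluated in the cancellation-free form
    r* = (lo + hi - b lo hi) / (1 + sqrt((1 - b lo)(1 - b hi))),
    which tends to the arithmetic midpoint as b -> 0.
    """
    if not 0.0 < b < 1.0:
        raise ValueError("bias b must lie in (0, 1)")
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError("references must satisfy 0 <= lo <= hi <= 1")
    if lo == hi:
        return lo
    p = (1.0 - b * lo) * (1.0 - b * hi)
    return (lo + hi - b * lo * hi) / (1.0 + math.sqrt(p))


def noiseless_levels(b: float) -> dict[float, float]:
    """Closed-form fixed points of the 3-round recursion for a noiseless observer.

    Satisfies g(r_level; b) = level to machine precision at every level.
    """
    r12 = midpoint_r(0.0, 1.0, b)
    r14 = midpoint_r(0.0, r12, b)
    r34 = midpoint_r(r12, 1.0, b)
    return {
        0.125: midpoint_r(0.0, r14, b),
        0.25: r14,
        0.375: midpoint_r(r14, r12, b),
        0.5: r12,
        0.625: midpoint_r(r12, r34, b),
        0.75: r34,
        0.875: midpoint_r(r34, 1.0, b),
    }


def run_bisection_rep(
    lo: float,
    hi: float,
    observer: ObserverParams,
    cfg: BisectionConfig = BisectionConfig(),
    rng: np.random.Generator | None = None,
) -> float:
    """One simulated adjustment rep; returns the estimated midpoint correlation.

    The test starts ``cfg.start_offset`` inside a randomly chosen
    reference, then walks toward the perceived midpoint with random step
    sizes in (0, (hi-lo)/10].  Both references and the test are
    re-perceived with fresh noise at every adjustment.  The returned
    estimate lies strictly between the references.
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("references must satisfy 0 <= lo < hi <= 1")
    rng = np.random.default_rng() if rng is None else rng
    span = hi - lo
    offset = min(cfg.start_offset, span / 2.0)
    margin = span * 1e-3
    test = (lo + offset) if rng.integers(2) == 0 else (hi - offset)

    prev_dir = 0
    reversals: list[float] = []
    trace: list[float] = []
    for _ in range(cfg.max_adjustments):
        p_test = percept(test, observer, rng)
        p_mid = 0.5 * (percept(lo, observer, rng) + percept(hi, observer, rng))
        step_dir = -1 if p_test > p_mid else 1
        if prev_dir != 0 and step_dir != prev_dir:
            reversals.append(test)
            if cfg.policy == "reversal" and len(reversals) >= cfg.max_reversals:
                break
        prev_dir = step_dir
        step = rng.uniform(0.0, span * cfg.step_frac)
        test = min(max(test + step_dir * step, lo + margin), hi - margin)
        trace.append(test)

    if cfg.policy == "time_average":
        est = float(np.mean(trace[cfg.burn_in:]))
    elif len(reversals) >= cfg.reversal_tail:
        est = float(np.mean(reversals[-cfg.reversal_tail:]))
    else:
        est = test
    return min(max(est, lo + margin), hi - margin)


def run_protocol(
    observer: ObserverParams,
    cfg: BisectionConfig = BisectionConfig(),
    rng: np.random.Generator | None = None,
) -> BisectionProtocolResult:
    """Three-round recursive bisection yielding the seven g = i/8 levels.

    Round 1 estimates g = 1/2 between r = 0 and r = 1; round 2 reuses
    that estimate as a reference for g = 1/4 and 3/4; round 3 fills in
    the eighths.  Each level is the mean of ``cfg.reps_per_level`` reps;
    sub-condition order within a round is randomized.
    """
    rng = np.random.default_rng() if rng is None else rng
    reps: dict[float, list[float]] = {}

    def estimate(level: float, lo: float, hi: float) -> float:
        vals = [run_bisection_rep(lo, hi, observer, cfg, rng)
                for _ in range(cfg.reps_per_level)]
        reps[level] = vals
        return float(np.mean(vals))

    r12 = estimate(0.5, 0.0, 1.0)

    round2 = [(0.25, 0.0, r12), (0.75, r12, 1.0)]
    rng.shuffle(round2)
    out: dict[float, float] = {0.5: r12}
    for level, lo, hi in round2:
        out[level] = estimate(level, lo, hi)

    round3 = [
        (0.125, 0.0, out[0.25]),
        (0.375, out[0.25], r12),
        (0.625, r12, out[0.75]),
        (0.875, out[0.75], 1.0),
    ]
    rng.shuffle(round3)
    for level, lo, hi in round3:
        out[level] = estimate(level, lo, hi)

    estimates = {level: out[level] for level in LEVELS}
    return BisectionProtocolResult(estimates=estimates, reps=reps)
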