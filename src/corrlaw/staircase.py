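"""Adaptive staircase estimation of correlation JNDs.

A transformed up-down procedure with asymmetric steps: the difference
between base and test correlation starts at 0.1, shrinks by 0.01 after a
correct 2AFC response and grows by 0.03 after an error, so the staircase
equilibrates where p_correct * 0.01 = (1 - p_correct) * 0.03, i.e. at
75% accuracy — the conventional JND criterion.  Convergence is declared
from a moving 24-trial window split into three sub-windows of eight: when
the variance of the sub-window means divided by the mean within-sub-window
variance falls to 0.25 or below, or after 52 trials, the run halts and the
JND is the average of the three sub-window means of the final window.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .observer import ObserverParams, discriminate

__all__ = [
    "StaircaseConfig",
    "Trial",
    "StaircaseRun",
    "convergence_ratio",
    "run_staircase",
    "run_condition",
    "DEFAULT_BASES",
    "BELOW_MIN_BASE",
]

DEFAULT_BASES: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(10))
# floor effects: no below-direction runs for base correlations under this
BELOW_MIN_BASE = 0.3


@dataclass(frozen=True)
class StaircaseConfig:
    start_offset: float = 0.1
    step_correct: float = -0.01
    step_incorrect: float = 0.03
    window: int = 24
    subwindows: int = 3
    ratio_threshold: float = 0.25
    max_trials: int = 52
    min_difference: float = 0.01

    def __post_init__(self) -> None:
        if self.window % self.subwindows != 0:
            raise ValueError("window must divide evenly into subwindows")
        if self.max_trials < self.window:
            raise ValueError("max_trials must be at least one full window")
        if self.step_correct >= 0 or self.step_incorrect <= 0:
            raise ValueError("step_correct must shrink and step_incorrect grow")


class Trial(NamedTuple):
    test_r: float
    difference: float
    correct: bool


@dataclass
class StaircaseRun:
    """Per-trial record of one JND measurement run."""

    base_r: float
    direction: str
    trials: list[Trial]
    jnd: float
    converged: bool
    n_trials: int
    observer_id: int = 0


def convergence_ratio(
    window_differences: Sequence[float], subwindows: int = 3
) -> float:
    """Between-sub-window variance of means over mean within-sub-window variance.

    Sample variances (ddof=1) throughout.  Zero within-variance is the
    degenerate steady state (the staircase is pinned) and is reported as
    a ratio of 0, i.e. converged.
    """
    d = np.asarray(window_differences, dtype=float)
    if d.ndim != 1:
        raise ValueError("expected a flat sequence of differences")
    if d.size % subwindows != 0 or d.size // subwindows < 2:
        raise ValueError(
            f"window must split into {subwindows} sub-windows of >= 2 trials"
        )
    sub = d.reshape(subwindows, -1)
    between = float(np.var(sub.mean(axis=1), ddof=1))
    within = float(np.mean(np.var(sub, axis=1, ddof=1)))
    if within == 0.0:
        return 0.0
    return between / within


def run_staircase(
    base_r: float,
    direction: str,
    observer: ObserverParams,
    cfg: StaircaseConfig = StaircaseConfig(),
    rng: np.random.Generator | None = None,
    observer_id: int = 0,
    respond=None,
) -> StaircaseRun:
    """Run one adaptive staircase and estimate the JND at ``base_r``.

    Test correlations are clamped between the base and the relevant
    range limit (1 from above, 0 from below), and the difference never
    drops under ``cfg.min_difference`` (a zero difference would make the
    trial undefined).  ``direction='below'`` is rejected at base 0.

    ``respond`` optionally replaces the simulated observer's 2AFC: a
    callable ``(r1, r2, rng) -> 0 | 1`` returning the index of the plot
    judged more correlated (useful for scripted response sequences).
    """
    if not 0.0 <= base_r <= 1.0:
        raise ValueError("base_r must lie in [0, 1]")
    if direction == "above":
        room = 1.0 - base_r
    elif direction == "below":
        room = base_r
    else:
        raise ValueError("direction must be 'above' or 'below'")
    if room < cfg.min_difference:
        raise ValueError(
            f"no room to test {direction} base correlation {base_r}"
        )
    rng = np.random.default_rng() if rng is None else rng

    diff = min(cfg.start_offset, room)
    trials: list[Trial] = []
    diffs: list[float] = []
    converged = False
    for _ in range(cfg.max_trials):
        test_r = base_r + diff if direction == "above" else base_r - diff
        if respond is None:
            choice = discriminate(base_r, test_r, observer, rng)
        else:
            choice = respond(base_r, test_r, rng)
        # correct = picked the genuinely more-correlated plot
        correct = (choice == 1) if direction == "above" else (choice == 0)
        trials.append(Trial(test_r, diff, correct))
        diffs.append(diff)
        diff += cfg.step_correct if correct else cfg.step_incorrect
        diff = min(max(diff, cfg.min_difference), room)
        if len(diffs) >= cfg.window:
            ratio = convergence_ratio(diffs[-cfg.window:], cfg.subwindows)
            if ratio <= cfg.ratio_threshold:
                converged = True
                break

    window = np.asarray(diffs[-cfg.window:])
    jnd = float(window.reshape(cfg.subwindows, -1).mean(axis=1).mean())
    return StaircaseRun(
        base_r=base_r,
        direction=direction,
        trials=trials,
        jnd=jnd,
        converged=converged,
        n_trials=len(trials),
        observer_id=observer_id,
    )


def run_condition(
    bases: Sequence[float],
    observer: ObserverParams,
    cfg: StaircaseConfig = StaircaseConfig(),
    n_observers: int = 1,
    rng: np.random.Generator | None = None,
    below_min_base: float = BELOW_MIN_BASE,
) -> list[StaircaseRun]:
    """One run per (simulated observer x base x admissible direction).

    Every base is tested from above; bases at or beyond ``below_min_base``
    are additionally tested from below (floor-effect rule).  All observers
    share ``observer``'s parameters but respond with independent noise.
    """
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    runs: list[StaircaseRun] = []
    for obs_id in range(n_observers):
        for base in bases:
            runs.append(
                run_staircase(base, "above", observer, cfg, rng, observer_id=obs_id)
            )
            if base >= below_min_base:
                runs.append(
                    run_staircase(
                        base, "below", observer, cfg, rng, observer_id=obs_id
                    )
                )
    return runs


def runs_to_csv(runs: Sequence[StaircaseRun], path: str | Path) -> None:
    """One row per trial: run_id, observer, base_r, direction, trial, test_r, difference, correct."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["run_id", "observer", "base_r", "direction", "trial",
             "test_r", "difference", "correct"]
        )
        for run_id, run in enumerate(runs):
            for t, trial in enumerate(run.trials):
                writer.writerow(
                    [run_id, run.observer_id, run.base_r, run.direction, t,
                     f"{trial.test_r:.6f}", f"{trial.difference:.6f}",
                     int(trial.correct)]
                )


def runs_summary_json(runs: Sequence[StaircaseRun], path: str | Path | None = None) -> str:
    summary = [
        {
            "observer": r.observer_id,
            "base_r": r.base_r,
            "direction": r.direction,
            "jnd": r.jnd,
            "converged": r.converged,
            "n_trials": r.n_trials,
        }
        for r in runs
    ]
    s = json.dumps(summary, indent=2)
    if path is not None:
        Path(path).write_text(s)
    return s
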