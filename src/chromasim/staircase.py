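"""Transformed up-down adaptive staircases.

A 2-down/1-up rule makes the stimulus harder (smaller letter, lower
contrast) after two consecutive correct responses and easier after any
error; its asymptotic convergence point is the level where
p(correct)^2 = 0.5, i.e. the ~70.7%-correct level.  Steps are either
multiplicative (contrast, factor 1.3) or additive (letter size in logMAR).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["StaircaseConfig", "TrialRecord", "run_staircase", "two_down_one_up_target"]


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of one adaptive run.

    ``step_mode='multiplicative'`` divides/multiplies the level by ``step``
    (must be > 1); ``'additive'`` subtracts/adds ``step``.  Levels are
    clipped to ``[min_level, max_level]`` when given.
    """

    start_level: float
    step: float = 1.3
    step_mode: str = "multiplicative"
    n_down: int = 2
    n_up: int = 1
    n_trials: int = 40
    min_level: float | None = None
    max_level: float | None = None
    task: str = ""

    def __post_init__(self):
        if self.step_mode not in ("multiplicative", "additive"):
            raise ValueError("step_mode must be 'multiplicative' or 'additive'")
        if self.step_mode == "multiplicative" and not self.step > 1:
            raise ValueError("multiplicative step factor must exceed 1")
        if self.step_mode == "additive" and not self.step > 0:
            raise ValueError("additive step must be positive")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")


@dataclass(frozen=True)
class TrialRecord:
    """One trial: the level shown, the response, and its correctness."""

    task: str
    level: float
    alternative: int
    response: int
    correct: bool
    index: int


def run_staircase(
    config: StaircaseConfig,
    responder: Callable[[float], bool],
    rng_seed: int | None = None,
    n_alternatives: int = 4,
) -> list[TrialRecord]:
    """Run one transformed up-down staircase against a responder.

    ``responder(level) -> bool`` decides correctness (simulated observers
    close over their own seeded generators, so identical seeds reproduce
    identical trial sequences).  The staircase's own generator (``rng_seed``)
    only picks which alternative is nominally presented, for bookkeeping.

    Raises
    ------
    ValueError
        If the level becomes non-finite (misconfigured steps/bounds).
    """
    rng = np.random.default_rng(rng_seed)
    level = float(config.start_level)
    records: list[TrialRecord] = []
    run_correct = 0
    for i in range(config.n_trials):
        if not np.isfinite(level) or (config.step_mode == "multiplicative" and level <= 0):
            raise ValueError(f"staircase level became invalid at trial {i}: {level}")
        alternative = int(rng.integers(n_alternatives))
        correct = bool(responder(level))
        response = alternative if correct else int((alternative + 1 + rng.integers(n_alternatives - 1)) % n_alternatives)
        records.append(
            TrialRecord(
                task=config.task,
                level=level,
                alternative=alternative,
                response=response,
                correct=correct,
                index=i,
            )
        )
        if correct:
            run_correct += 1
            if run_correct >= config.n_down:
                level = _step_down(level, config)
                run_correct = 0
        else:
            run_correct = 0
            level = _step_up(level, config)
        level = _clip(level, config)
    return records


def _step_down(level: float, c: StaircaseConfig) -> float:
    return level / c.step if c.step_mode == "multiplicative" else level - c.step


def _step_up(level: float, c: StaircaseConfig) -> float:
    return level * c.step if c.step_mode == "multiplicative" else level + c.step


def _clip(level: float, c: StaircaseConfig) -> float:
    if c.min_level is not None:
        level = max(level, c.min_level)
    if c.max_level is not None:
        level = min(level, c.max_level)
    return level


def two_down_one_up_target() -> float:
    """Probability-correct tracked by a 2-down/1-up rule (sqrt(0.5) = 0.707)."""
    return float(np.sqrt(0.5))
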