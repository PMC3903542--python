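"""Two-phase 2AFC data collection: interleaved staircases, then MOCS.

The design crosses background symmetry (symmetric gray, symmetric blue, or
asymmetric gray|blue) with presentation timing (simultaneous or a 2 s
delay), optionally with distractor patches shown during the delay.  The
four named conditions are:

- ``baseline``   — symmetric backgrounds, simultaneous;
- ``constancy``  — asymmetric backgrounds, simultaneous;
- ``memory``     — symmetric backgrounds, 2 s delay;
- ``joint``      — asymmetric backgrounds, 2 s delay.

Symmetric conditions are run one background color per block, so a full
condition comprises a gray block and a blue block.  In asymmetric blocks the
gray field is always on the left and the blue field on the right, so the
reference's background determines its side; both reference-background
assignments are interleaved within the block.

Phase 1 runs four interleaved weighted up-down staircases per cell (targets
at the 20th and 80th percentiles, starting above and below the reference),
20 trials each, for each of three reference hues — 240 trials for a uniform
background block and 480 for an asymmetric block.  Phase 2 presents five
fixed test levels per cell, spanning the staircase fit's 1st–99th
percentiles, with the method of constant stimuli.

Presentation durations (500 ms) and the 2 s delay are design metadata only:
the simulation has no real-time behavior, and timing enters the model solely
through the remembered/simultaneous distinction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import InvalidParameterError, StaircaseExhaustedError
from .observer import BLUE, GRAY, StimulusPresentation

__all__ = [
    "Condition",
    "CONDITIONS",
    "StaircaseState",
    "TRIAL_COLUMNS",
    "run_staircase_block",
    "staircase_update",
    "select_mocs_levels",
    "run_mocs_block",
    "sample_distractors",
    "mocs_needs_adjustment",
]

#: canonical trial-table column order (see io.py for the on-disk schema)
TRIAL_COLUMNS = [
    "trial_index",
    "condition",
    "phase",
    "block_background",
    "reference_hue",
    "test_hue",
    "reference_background",
    "reference_side",
    "staircase_id",
    "distractor1_hue",
    "distractor2_hue",
    "response_test_bluer",
    "seed",
]

Observer = Callable[[StimulusPresentation, StimulusPresentation, np.random.Generator], bool]

_SYMMETRIES = ("symmetric_gray", "symmetric_blue", "asymmetric")


@dataclass(frozen=True)
class Condition:
    """One experimental block type (background symmetry x timing x distractors)."""

    background_symmetry: str
    delay: str = "simultaneous"  # "simultaneous" | "delay_2s"
    distractors: str = "none"  # "none" | "present"

    def __post_init__(self) -> None:
        if self.background_symmetry not in _SYMMETRIES:
            raise InvalidParameterError(
                f"background_symmetry must be one of {_SYMMETRIES}, got {self.background_symmetry!r}"
            )
        if self.delay not in ("simultaneous", "delay_2s"):
            raise InvalidParameterError(f"invalid delay {self.delay!r}")
        if self.distractors not in ("none", "present"):
            raise InvalidParameterError(f"invalid distractors {self.distractors!r}")
        if self.distractors == "present" and self.delay != "delay_2s":
            raise InvalidParameterError("distractors require a delay condition")

    @property
    def delayed(self) -> bool:
        return self.delay == "delay_2s"

    @property
    def symmetric(self) -> bool:
        return self.background_symmetry != "asymmetric"

    @property
    def block_background(self) -> str:
        """'gray', 'blue' or 'asymmetric'."""
        if self.background_symmetry == "symmetric_gray":
            return GRAY
        if self.background_symmetry == "symmetric_blue":
            return BLUE
        return "asymmetric"

    @property
    def name(self) -> str:
        """Condition family name: baseline/constancy/memory/joint [+ _distractors]."""
        if self.symmetric:
            base = "memory" if self.delayed else "baseline"
        else:
            base = "joint" if self.delayed else "constancy"
        return base + ("_distractors" if self.distractors == "present" else "")

    def reference_backgrounds(self) -> tuple[str, ...]:
        """Reference-background contexts collected within one block."""
        if self.symmetric:
            return (self.block_background,)
        return (GRAY, BLUE)


def _condition_blocks(name: str) -> tuple[Condition, ...]:
    """Blocks making up one named condition family."""
    distract = "present" if name.endswith("_distractors") else "none"
    base = name.removesuffix("_distractors")
    delay = "delay_2s" if base in ("memory", "joint") else "simultaneous"
    if base in ("baseline", "memory"):
        return (
            Condition("symmetric_gray", delay, distract),
            Condition("symmetric_blue", delay, distract),
        )
    if base in ("constancy", "joint"):
        return (Condition("asymmetric", delay, distract),)
    raise InvalidParameterError(f"unknown condition name {name!r}")


#: the six blocked condition families
CONDITIONS = (
    "baseline",
    "constancy",
    "memory",
    "memory_distractors",
    "joint",
    "joint_distractors",
)
Condition.blocks_for = staticmethod(_condition_blocks)


# ---------------------------------------------------------------------------
# Staircase
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StaircaseState:
    """State of one weighted up-down staircase.

    The staircase targets the 20th or 80th percentile of the psychometric
    function.  The test level always moves down (yellower) after a "test
    bluer" response and up after a "test not bluer" response; the up/down
    step sizes are asymmetric in the ratio ``p/(1-p)`` so the asymptotic
    convergence point is the target percentile.  The base step starts at
    ``initial_factor`` times the final step and is halved at each of the
    first two reversals (floored at the final step).
    """

    target_percentile: float
    current_level: float
    final_step: float
    initial_factor: float = 3.0
    max_trials: int = 20
    trials_completed: int = 0
    reversal_levels: tuple[float, ...] = ()
    last_move: int = 0  # +1, -1, or 0 before any trial

    def __post_init__(self) -> None:
        if self.target_percentile not in (0.2, 0.8):
            raise InvalidParameterError(
                f"target_percentile must be 0.2 or 0.8, got {self.target_percentile!r}"
            )
        if not self.final_step > 0:
            raise InvalidParameterError("final_step must be > 0")
        if not self.initial_factor >= 1:
            raise InvalidParameterError("initial_factor must be >= 1")
        if self.max_trials < 1:
            raise InvalidParameterError("max_trials must be >= 1")

    @property
    def base_step(self) -> float:
        """Current base step: halved at the first two reversals."""
        halvings = min(len(self.reversal_levels), 2)
        factor = max(1.0, self.initial_factor / (2.0**halvings))
        return self.final_step * factor

    def step_sizes(self) -> tuple[float, float]:
        """(step_up, step_down): asymmetric so equilibrium is the target.

        At equilibrium ``p * step_down == (1 - p) * step_up``; the smaller
        of the two steps equals :attr:`base_step`.
        """
        p = self.target_percentile
        ratio = p / (1.0 - p)  # step_up / step_down
        base = self.base_step
        step_up = base * max(1.0, ratio)
        step_down = base * max(1.0, 1.0 / ratio)
        return step_up, step_down

    @property
    def exhausted(self) -> bool:
        return self.trials_completed >= self.max_trials


def staircase_update(state: StaircaseState, response_test_bluer: bool) -> StaircaseState:
    """Advance a staircase by one trial; returns the new state.

    The presented level is ``state.current_level``; a reversal is recorded
    at that level whenever the movement direction flips.
    """
    if state.exhausted:
        raise StaircaseExhaustedError(
            f"staircase already completed {state.max_trials} trials"
        )
    move = -1 if response_test_bluer else +1
    reversals = state.reversal_levels
    if state.last_move != 0 and move != state.last_move:
        reversals = reversals + (state.current_level,)
    step_up, step_down = replace(state, reversal_levels=reversals).step_sizes()
    delta = step_up if move > 0 else -step_down
    return replace(
        state,
        current_level=state.current_level + delta,
        trials_completed=state.trials_completed + 1,
        reversal_levels=reversals,
        last_move=move,
    )


def sample_distractors(
    reference_hue: float,
    sd: float,
    rng: np.random.Generator,
    *,
    offset: float = 0.2,
) -> tuple[float, float]:
    """Two distractor hues ~ Normal(reference_hue - offset, sd^2).

    The distractor distribution sits 0.2 radians (about 1.5 average JNDs)
    toward smaller (yellower) hue angles from the reference.
    """
    if sd < 0:
        raise InvalidParameterError(f"distractor sd must be >= 0, got {sd!r}")
    mean = reference_hue - offset
    return float(mean + sd * rng.standard_normal()), float(mean + sd * rng.standard_normal())


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class _Cell:
    reference_hue: float
    reference_background: str


def _trial_row(
    condition: Condition,
    phase: str,
    trial_index: int,
    cell: _Cell,
    test_hue: float,
    staircase_id,
    observer: Observer,
    rng: np.random.Generator,
    distractor_sd: float,
    distractor_offset: float,
    seed_label: int,
) -> dict:
    if condition.symmetric:
        test_background = cell.reference_background
        side = "left" if rng.random() < 0.5 else "right"
    else:
        # gray field left, blue field right: the background fixes the side
        test_background = BLUE if cell.reference_background == GRAY else GRAY
        side = "left" if cell.reference_background == GRAY else "right"
    if condition.distractors == "present":
        d1, d2 = sample_distractors(
            cell.reference_hue, distractor_sd, rng, offset=distractor_offset
        )
    else:
        d1 = d2 = math.nan
    reference = StimulusPresentation(
        cell.reference_hue,
        cell.reference_background,
        interval="first",
        remembered=condition.delayed,
    )
    test = StimulusPresentation(test_hue, test_background, interval="second")
    response = bool(observer(reference, test, rng))
    return {
        "trial_index": trial_index,
        "condition": condition.name,
        "phase": phase,
        "block_background": condition.block_background,
        "reference_hue": cell.reference_hue,
        "test_hue": test_hue,
        "reference_background": cell.reference_background,
        "reference_side": side,
        "staircase_id": staircase_id,
        "distractor1_hue": d1,
        "distractor2_hue": d2,
        "response_test_bluer": response,
        "seed": seed_label,
    }


def run_staircase_block(
    observer: Observer,
    condition: Condition,
    reference_hues: Sequence[float],
    seed,
    *,
    trials_per_staircase: int = 20,
    final_step: float = 0.06,
    initial_factor: float = 3.0,
    start_offset: float = 0.3,
    distractor_sd: float = 0.067,
    distractor_offset: float = 0.2,
    seed_label: int = 0,
) -> pd.DataFrame:
    """Run the interleaved-staircase phase for one block.

    Four staircases per (reference hue x reference background) cell: targets
    {20%, 80%} crossed with starting points below/above the reference.  With
    three references this yields 12 staircases (240 trials) for a uniform
    background block and 24 staircases (480 trials) for an asymmetric block.
    The interleaving order is a seeded random permutation in which every
    staircase is advanced exactly ``trials_per_staircase`` times.
    """
    refs = [float(r) for r in reference_hues]
    if len(refs) != 3:
        raise InvalidParameterError(f"exactly 3 reference hues required, got {len(refs)}")
    rng = _as_rng(seed)

    staircases: list[StaircaseState] = []
    cells: list[_Cell] = []
    for background in condition.reference_backgrounds():
        for ref in refs:
            cell = _Cell(ref, background)
            for target in (0.2, 0.8):
                for sign in (-1.0, +1.0):
                    staircases.append(
                        StaircaseState(
                            target_percentile=target,
                            current_level=ref + sign * start_offset,
                            final_step=final_step,
                            initial_factor=initial_factor,
                            max_trials=trials_per_staircase,
                        )
                    )
                    cells.append(cell)

    schedule = np.repeat(np.arange(len(staircases)), trials_per_staircase)
    rng.shuffle(schedule)

    rows = []
    for trial_index, sid in enumerate(schedule):
        sid = int(sid)
        state = staircases[sid]
        row = _trial_row(
            condition, "staircase", trial_index, cells[sid], state.current_level,
            sid, observer, rng, distractor_sd, distractor_offset, seed_label,
        )
        rows.append(row)
        staircases[sid] = staircase_update(state, row["response_test_bluer"])

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def select_mocs_levels(stair_fit, n_levels: int = 5, coverage: float = 0.98):
    """Evenly spaced MOCS test levels spanning the staircase-phase fit.

    Operationalizes "roughly 0 and 100% selection probability" as the 1st
    and 99th percentiles of the fitted cumulative normal (``coverage``
    0.98); returns ``n_levels`` strictly increasing hues.
    """
    location = float(stair_fit.location)
    spread = float(stair_fit.spread)
    if not spread > 0 or not math.isfinite(spread):
        raise InvalidParameterError(f"fit spread must be positive and finite, got {spread!r}")
    if n_levels < 2:
        raise InvalidParameterError("n_levels must be >= 2")
    if not 0 < coverage < 1:
        raise InvalidParameterError("coverage must be in (0, 1)")
    tail = (1.0 - coverage) / 2.0
    z = np.linspace(norm.ppf(tail), norm.ppf(1.0 - tail), n_levels)
    return location + spread * z


def run_mocs_block(
    observer: Observer,
    condition: Condition,
    levels: Mapping[tuple[float, str], Sequence[float]],
    repetitions: int,
    seed,
    *,
    distractor_sd: float = 0.067,
    distractor_offset: float = 0.2,
    seed_label: int = 0,
    trial_index_start: int = 0,
) -> pd.DataFrame:
    """Run one method-of-constant-stimuli block.

    ``levels`` maps ``(reference_hue, reference_background)`` to that cell's
    test levels.  Every (cell x level) pair is presented exactly
    ``repetitions`` times, in a seeded random order interleaving references,
    backgrounds, and levels.
    """
    if repetitions < 1:
        raise InvalidParameterError("repetitions must be >= 1")
    if not levels:
        raise InvalidParameterError("levels mapping is empty")
    rng = _as_rng(seed)

    plan: list[tuple[_Cell, float]] = []
    for (ref, background), cell_levels in levels.items():
        if background not in condition.reference_backgrounds():
            raise InvalidParameterError(
                f"reference background {background!r} not part of this block"
            )
        for level in cell_levels:
            plan.extend([(_Cell(float(ref), background), float(level))] * repetitions)
    order = rng.permutation(len(plan))

    rows = []
    for i, idx in enumerate(order):
        cell, level = plan[int(idx)]
        rows.append(
            _trial_row(
                condition, "mocs", trial_index_start + i, cell, level, pd.NA,
                observer, rng, distractor_sd, distractor_offset, seed_label,
            )
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def mocs_needs_adjustment(
    test_hues: Sequence[float],
    n_trials: Sequence[int],
    n_test_bluer: Sequence[int],
) -> bool:
    """Whether a second MOCS pass with an adjusted range is warranted.

    The range is considered too narrow when either extreme level's observed
    proportion lies strictly inside (0.25, 0.75), i.e. the levels fail to
    pin down the psychometric function's tails.
    """
    hues = np.asarray(test_hues, dtype=float)
    n = np.asarray(n_trials, dtype=float)
    k = np.asarray(n_test_bluer, dtype=float)
    if hues.size < 2:
        raise InvalidParameterError("need at least two levels")
    order = np.argsort(hues)
    for idx in (order[0], order[-1]):
        if n[idx] > 0:
            p = k[idx] / n[idx]
            if 0.25 < p < 0.75:
                return True
    return False
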