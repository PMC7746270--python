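"""Trial-schedule generation and adaptive luminance staircases.

The session interleaves four contrast conditions — no stimulus (zero
contrast), two low-contrast levels each driven by its own detection
staircase (2-up/1-down and 4-up/1-down), and a fixed high-contrast level —
for 567 trials in the default design (167/90/243/67). Stimulus trials move
at one of nine predetermined directions (0, +/-16, +/-32, +/-48, +/-64
degrees relative to a central reference) or, on a small fraction, in a
completely random direction. +/-32 deg is over-represented (58% of stimulus
trials vs. 36% for the other predetermined directions and 6% random),
which is what induces the learned bimodal prior.

Direction allocation is exact-count, not Bernoulli: the printed percentages
are reproduced exactly on every seed (58% of 400 stimulus trials = 232 at
+/-32, split 116/116 across signs; 6% = 24 random; the remaining 144 spread
as evenly as possible over the seven other predetermined directions, the
remainder assigned by seeded draw).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RANDOM_DIRECTION",
    "CONDITIONS",
    "TaskConfig",
    "TrialSpec",
    "TrialSchedule",
    "StaircaseState",
    "generate_schedule",
    "staircase_update",
]

#: marker used for trials whose direction is drawn uniformly at simulation time
RANDOM_DIRECTION = "RANDOM"

CONDITIONS = ("zero", "low_2_1", "low_4_1", "high")

#: predetermined directions other than the over-represented +/-32 deg
_OTHER_DIRECTIONS = (0.0, 16.0, -16.0, 48.0, -48.0, 64.0, -64.0)


@dataclass(frozen=True)
class TaskConfig:
    """Design of one session.

    Counts default to the study design (167 zero-contrast, 90 low-contrast
    on the 2/1 staircase, 243 on the 4/1 staircase, 67 high-contrast);
    direction percentages to 58/36/6. ``high_luminance`` is the fixed
    high-contrast intensity in cd/m^2 above background; staircase knobs
    (start level, multiplicative step on luminance, bounds) are explicit
    configuration, not study-reported values.
    """

    n_zero: int = 167
    n_low_2_1: int = 90
    n_low_4_1: int = 243
    n_high: int = 67
    pct_32: float = 58.0
    pct_other: float = 36.0
    pct_random: float = 6.0
    reference_angle: float = 0.0
    high_luminance: float = 1.76
    staircase_start: float = 0.5
    staircase_factor: float = 1.2
    luminance_bounds: tuple[float, float] = (0.01, 1.76)

    def __post_init__(self):
        if min(self.n_zero, self.n_low_2_1, self.n_low_4_1, self.n_high) <= 0:
            raise ValueError("all condition counts must be positive")
        total = self.pct_32 + self.pct_other + self.pct_random
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"direction percentages must sum to 100, got {total}")
        if min(self.pct_32, self.pct_other, self.pct_random) < 0:
            raise ValueError("direction percentages must be nonnegative")
        lo, hi = self.luminance_bounds
        if not 0 < lo < hi:
            raise ValueError("luminance bounds must satisfy 0 < low < high")
        if self.staircase_factor <= 1.0:
            raise ValueError("staircase factor must exceed 1")

    @property
    def n_stimulus(self) -> int:
        return self.n_low_2_1 + self.n_low_4_1 + self.n_high

    @property
    def n_trials(self) -> int:
        return self.n_zero + self.n_stimulus

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["luminance_bounds"] = list(self.luminance_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "luminance_bounds" in d:
            d["luminance_bounds"] = tuple(d["luminance_bounds"])
        return cls(**d)


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: condition plus (for stimulus trials) a direction.

    ``direction_deg`` is relative to the central reference; ``None`` for
    zero-contrast trials and :data:`RANDOM_DIRECTION` for random-direction
    trials. ``luminance`` is filled at simulation time for staircased trials.
    """

    index: int
    condition: str
    direction_deg: float | str | None = None
    luminance: float | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if (self.direction_deg is None) != (self.condition == "zero"):
            raise ValueError("direction present iff the trial has a stimulus")


@dataclass(frozen=True)
class TrialSchedule:
    trials: tuple[TrialSpec, ...]
    seed: int
    design: TaskConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            d = ("" if t.direction_deg is None
                 else RANDOM_DIRECTION if t.direction_deg == RANDOM_DIRECTION
                 else t.direction_deg)
            sid = {"low_2_1": "2_1", "low_4_1": "4_1"}.get(t.condition, "")
            rows.append({"trial_index": t.index, "condition": t.condition,
                         "direction_deg": d, "staircase_id": sid})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class StaircaseState:
    """An n-up/1-down luminance staircase.

    The level steps down (harder) only after ``n_up`` consecutive correct
    detections and steps up (easier) after any single miss; steps are
    multiplicative by ``factor`` and the level is clamped to ``bounds``.
    """

    rule: str  # "two_up_one_down" | "four_up_one_down"
    current_level: float
    factor: float = 1.2
    bounds: tuple[float, float] = (0.01, 1.76)
    run_length: int = 0
    history: tuple[tuple[float, bool], ...] = ()

    _N_UP = {"two_up_one_down": 2, "four_up_one_down": 4}

    def __post_init__(self):
        if self.rule not in self._N_UP:
            raise ValueError(f"unknown staircase rule {self.rule!r}")
        if self.current_level <= 0:
            raise ValueError("staircase level must be positive")

    @property
    def n_up(self) -> int:
        return self._N_UP[self.rule]


def staircase_update(state: StaircaseState, detected_correctly: bool) -> StaircaseState:
    """Advance a staircase by one trial outcome; returns a new state."""
    lo, hi = state.bounds
    level = state.current_level
    if detected_correctly:
        run = state.run_length + 1
        if run >= state.n_up:
            level = max(lo, level / state.factor)
            run = 0
    else:
        run = 0
        level = min(hi, level * state.factor)
    return replace(state, current_level=level, run_length=run,
                   history=state.history + ((state.current_level, detected_correctly),))


def _allocate_directions(n_stim: int, config: TaskConfig,
                         rng: np.random.Generator) -> list:
    n32 = round(n_stim * config.pct_32 / 100.0)
    nrand = round(n_stim * config.pct_random / 100.0)
    nother = n_stim - n32 - nrand
    if min(n32, nrand, nother) < 0:
        raise ValueError("direction percentages inconsistent with trial counts")

    dirs: list = []
    dirs += [32.0] * (n32 - n32 // 2) + [-32.0] * (n32 // 2)
    base, rem = divmod(nother, len(_OTHER_DIRECTIONS))
    for d in _OTHER_DIRECTIONS:
        dirs += [d] * base
    extra = rng.choice(len(_OTHER_DIRECTIONS), size=rem, replace=False)
    dirs += [_OTHER_DIRECTIONS[i] for i in extra]
    dirs += [RANDOM_DIRECTION] * nrand
    return dirs


def generate_schedule(config: TaskConfig | None = None, seed: int = 0) -> TrialSchedule:
    """Build a randomly interleaved trial schedule for one session.

    Deterministic for a given ``(config, seed)``: condition order, the
    direction list and its assignment to stimulus trials are all drawn from
    a single seeded generator.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)

    cond_pool = (["zero"] * config.n_zero + ["low_2_1"] * config.n_low_2_1
                 + ["low_4_1"] * config.n_low_4_1 + ["high"] * config.n_high)
    order = rng.permutation(len(cond_pool))
    conditions = [cond_pool[i] for i in order]

    dirs = _allocate_directions(config.n_stimulus, config, rng)
    dirs = [dirs[i] for i in rng.permutation(len(dirs))]

    trials, j = [], 0
    for i, cond in enumerate(conditions):
        if cond == "zero":
            trials.append(TrialSpec(index=i, condition=cond))
        else:
            lum = config.high_luminance if cond == "high" else None
            trials.append(TrialSpec(index=i, condition=cond,
                                    direction_deg=dirs[j], luminance=lum))
            j += 1
    return TrialSchedule(trials=tuple(trials), seed=seed, design=config)
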