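"""Task schedules for the dual-valence volatility learning task.

The task presents two shapes (``A``/``B``); on every trial one shape carries a
monetary win and one a loss, positioned independently.  A session has three
80-trial blocks: in block 1 both outcome probabilities are volatile, in blocks
2 and 3 exactly one is volatile while the other is held at 50%.  A volatile
trajectory alternates between 15% and 85% in runs of 14-30 trials and is
balanced so its mean over the block is exactly 50%; a stable trajectory is
constant at 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlockType",
    "BlockOrder",
    "BlockSpec",
    "OutcomeSchedule",
    "SessionSchedule",
    "generate_block",
    "generate_volatile_trajectory",
    "generate_session",
    "validate_schedule",
    "run_lengths",
]


class BlockType(str, Enum):
    BOTH_VOLATILE = "both_volatile"
    WIN_VOLATILE_LOSS_STABLE = "win_volatile_loss_stable"
    LOSS_VOLATILE_WIN_STABLE = "loss_volatile_win_stable"


class BlockOrder(str, Enum):
    WIN_VOLATILE_FIRST = "win_volatile_first"
    LOSS_VOLATILE_FIRST = "loss_volatile_first"


@dataclass(frozen=True)
class BlockSpec:
    """Parameters of one task block.

    Defaults are the study values: 80 trials, volatile levels 15%/85% in runs
    of 14-30 trials, stable level 50%.
    """

    block_type: BlockType = BlockType.BOTH_VOLATILE
    n_trials: int = 80
    volatile_levels: tuple[float, float] = (0.15, 0.85)
    stable_level: float = 0.50
    run_length_range: tuple[int, int] = (14, 30)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for p in (*self.volatile_levels, self.stable_level):
            if not 0.0 < p < 1.0:
                raise ValueError(f"probability {p} not in (0, 1)")
        lo, hi = self.run_length_range
        if not (0 < lo <= hi):
            raise ValueError("run_length_range must be ordered and positive")

    @property
    def win_volatile(self) -> bool:
        return self.block_type in (
            BlockType.BOTH_VOLATILE,
            BlockType.WIN_VOLATILE_LOSS_STABLE,
        )

    @property
    def loss_volatile(self) -> bool:
        return self.block_type in (
            BlockType.BOTH_VOLATILE,
            BlockType.LOSS_VOLATILE_WIN_STABLE,
        )


@dataclass
class OutcomeSchedule:
    """Per-trial outcome probabilities and realised outcome sides for a block.

    ``p_win_A[i]`` is the probability that the win sits under shape A on trial
    i (1-based trials throughout); ``win_side``/``loss_side`` are the realised
    placements, drawn independently per trial.
    """

    p_win_A: np.ndarray
    p_loss_A: np.ndarray
    win_side: np.ndarray  # array of "A"/"B"
    loss_side: np.ndarray
    block_type: BlockType = BlockType.BOTH_VOLATILE

    def __post_init__(self) -> None:
        n = len(self.p_win_A)
        for name in ("p_loss_A", "win_side", "loss_side"):
            if len(getattr(self, name)) != n:
                raise ValueError("all per-trial sequences must share one length")

    @property
    def n_trials(self) -> int:
        return len(self.p_win_A)

    @property
    def win_on_A(self) -> np.ndarray:
        """Indicator array: 1 where the win was realised under shape A."""
        return (np.asarray(self.win_side) == "A").astype(float)

    @property
    def loss_on_A(self) -> np.ndarray:
        return (np.asarray(self.loss_side) == "A").astype(float)

    def to_frame(self, block: int = 1) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": block,
                "trial": np.arange(1, self.n_trials + 1),
                "p_win_A": self.p_win_A,
                "p_loss_A": self.p_loss_A,
                "win_side": self.win_side,
                "loss_side": self.loss_side,
            }
        )


@dataclass
class SessionSchedule:
    """Three-block session: block 1 both-volatile, blocks 2-3 counterbalanced."""

    blocks: list[OutcomeSchedule]
    block_order: BlockOrder

    def __post_init__(self) -> None:
        if len(self.blocks) != 3:
            raise ValueError("a session has exactly 3 blocks")

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [b.to_frame(block=i + 1) for i, b in enumerate(self.blocks)],
            ignore_index=True,
        )


def run_lengths(trajectory: Sequence[float]) -> list[int]:
    """Lengths of maximal constant runs in a probability trajectory."""
    arr = np.asarray(trajectory)
    if arr.size == 0:
        return []
    change = np.flatnonzero(np.diff(arr) != 0)
    edges = np.concatenate([[-1], change, [arr.size - 1]])
    return list(np.diff(edges).astype(int))


def generate_volatile_trajectory(
    spec: BlockSpec, rng: np.random.Generator
) -> np.ndarray:
    """Alternating-level trajectory with exact 50% mean over the block.

    Run lengths are drawn uniformly from ``run_length_range`` until the block
    is filled; the final two runs are then adjusted so that the trials spent at
    each level are equal, rejecting and resampling whenever the adjusted runs
    fall outside the admissible range.  The starting level is a fair coin per
    stream.
    """
    n = spec.n_trials
    lo, hi = spec.run_length_range
    if n < 2 * lo:
        raise ValueError(
            f"n_trials={n} cannot fit two runs of minimum length {lo}"
        )
    if n % 2:
        raise ValueError(
            f"n_trials={n} is odd: exact 50/50 level balance is infeasible"
        )
    half = n // 2
    for _ in range(10_000):
        runs: list[int] = []
        while sum(runs) < n:
            runs.append(int(rng.integers(lo, hi + 1)))
        k = len(runs)
        if k < 2:
            continue
        # Runs alternate levels, so parity of the index identifies the level.
        # Fix the last two runs (one of each parity) to hit the exact balance.
        s_even = sum(runs[i] for i in range(0, k - 2) if i % 2 == 0)
        s_odd = sum(runs[i] for i in range(0, k - 2) if i % 2 == 1)
        if (k - 2) % 2 == 0:
            runs[k - 2] = half - s_even
            runs[k - 1] = half - s_odd
        else:
            runs[k - 2] = half - s_odd
            runs[k - 1] = half - s_even
        if lo <= runs[k - 2] <= hi and lo <= runs[k - 1] <= hi:
            levels = list(spec.volatile_levels)
            if rng.random() < 0.5:
                levels.reverse()
            traj = np.concatenate(
                [np.full(r, levels[i % 2]) for i, r in enumerate(runs)]
            )
            assert traj.size == n
            return traj
    raise RuntimeError(
        "could not construct a balanced volatile trajectory; "
        "check n_trials against run_length_range"
    )


def generate_block(spec: BlockSpec, seed: int | np.random.SeedSequence) -> OutcomeSchedule:
    """Generate one block: probability trajectories plus realised sides."""
    rng = np.random.default_rng(seed)
    if spec.win_volatile:
        p_win = generate_volatile_trajectory(spec, rng)
    else:
        p_win = np.full(spec.n_trials, spec.stable_level)
    if spec.loss_volatile:
        p_loss = generate_volatile_trajectory(spec, rng)
    else:
        p_loss = np.full(spec.n_trials, spec.stable_level)
    win_side = np.where(rng.random(spec.n_trials) < p_win, "A", "B")
    loss_side = np.where(rng.random(spec.n_trials) < p_loss, "A", "B")
    return OutcomeSchedule(p_win, p_loss, win_side, loss_side, spec.block_type)


def generate_session(
    order: BlockOrder | str, seed: int | np.random.SeedSequence
) -> SessionSchedule:
    """Three 80-trial blocks; block 1 both-volatile, blocks 2-3 per ``order``."""
    order = BlockOrder(order)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    child = ss.spawn(3)
    if order is BlockOrder.WIN_VOLATILE_FIRST:
        types = [
            BlockType.BOTH_VOLATILE,
            BlockType.WIN_VOLATILE_LOSS_STABLE,
            BlockType.LOSS_VOLATILE_WIN_STABLE,
        ]
    else:
        types = [
            BlockType.BOTH_VOLATILE,
            BlockType.LOSS_VOLATILE_WIN_STABLE,
            BlockType.WIN_VOLATILE_LOSS_STABLE,
        ]
    blocks = [
        generate_block(BlockSpec(block_type=t), s) for t, s in zip(types, child)
    ]
    return SessionSchedule(blocks, order)


def validate_schedule(sched: OutcomeSchedule, spec: BlockSpec) -> dict[str, bool]:
    """Per-invariant pass/fail report for a generated block.

    Checks the allowed probability levels, run-length bounds for volatile
    roles, and the exact-50% block mean.
    """
    report: dict[str, bool] = {}
    roles = {
        "win": (sched.p_win_A, spec.win_volatile),
        "loss": (sched.p_loss_A, spec.loss_volatile),
    }
    for name, (traj, volatile) in roles.items():
        if volatile:
            levels_ok = bool(np.isin(traj, spec.volatile_levels).all())
            runs = run_lengths(traj)
            lo, hi = spec.run_length_range
            runs_ok = all(lo <= r <= hi for r in runs)
            mean_ok = bool(abs(traj.mean() - 0.5) < 1e-9)
        else:
            levels_ok = bool((traj == spec.stable_level).all())
            runs_ok = True
            mean_ok = bool(abs(traj.mean() - 0.5) < 1e-9)
        report[f"{name}_levels"] = levels_ok
        report[f"{name}_run_lengths"] = runs_ok
        report[f"{name}_mean_50"] = mean_ok
    report["lengths_match"] = (
        len(sched.p_win_A)
        == len(sched.p_loss_A)
        == len(sched.win_side)
        == len(sched.loss_side)
    )
    report["passed"] = all(report.values())
    return report
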