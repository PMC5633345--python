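"""Synthetic cohorts: behavioural agents and matching raw pupil traces.

Agents draw choices from a model variant's per-trial choice probabilities on
a generated session schedule; earnings follow the task's 15p rule (+15 if the
chosen shape carries the win only, -15 if the loss only, 0 otherwise).

The pupil generator emulates a 500 Hz pupil-area recording: slow sinusoidal
drift + Gaussian noise + an outcome-locked gamma-shaped dilation per trial,
with blinks inserted as dropout intervals.  The obtained-vs-unobtained
amplitude difference of the dilation is injectable per valence and block
volatility, so the preprocessing chain can be validated by effect recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import ModelParams, model_variant_run
from .schedule import (
    BlockOrder,
    BlockType,
    SessionSchedule,
    generate_session,
)

__all__ = [
    "SessionData",
    "PupilGenParams",
    "PupilEffectSpec",
    "simulate_agent",
    "simulate_cohort",
    "simulate_pupil",
    "block_types_for_order",
]

WIN_PENCE = 15
LOSS_PENCE = -15


@dataclass
class SessionData:
    """One participant's choices and outcomes across the three blocks."""

    participant_id: str | int
    block_order: BlockOrder
    trials: pd.DataFrame  # block, trial, choice, win_side, loss_side, earnings_delta
    true_params: dict | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_earnings(self) -> int:
        return int(self.trials["earnings_delta"].sum())


@dataclass(frozen=True)
class PupilGenParams:
    """Generator settings for the synthetic 500 Hz pupil stream.

    Amplitudes are in the arbitrary pupil-area units of the raw trace (the
    z-transform in preprocessing removes the scale); the dilation kernel is a
    gamma density peaking ``(shape-1)*scale`` seconds after outcome onset
    with 6 s support, matching the analysed post-outcome window.
    """

    sampling_rate: float = 500.0
    kernel_shape: float = 3.0
    kernel_scale: float = 0.5  # peak at 1.0 s, most mass inside 6 s
    kernel_duration_s: float = 6.0
    base_amp_win: float = 0.6
    base_amp_loss: float = 1.0  # losses dilate more than wins
    noise_sd: float = 0.15
    drift_amplitude: float = 0.5
    drift_period_s: float = 90.0
    blink_rate_hz: float = 0.08
    blink_duration_range_s: tuple[float, float] = (0.1, 0.4)
    baseline_level: float = 5.0
    trial_duration_s: float = 9.0
    outcome_onset_s: float = 1.5

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lo, hi = self.blink_duration_range_s
        if not 0 < lo <= hi:
            raise ValueError("blink durations must be positive and ordered")
        if self.outcome_onset_s < 1.0:
            raise ValueError("need >= 1 s of pre-outcome baseline per trial")
        if self.outcome_onset_s + self.kernel_duration_s > self.trial_duration_s:
            raise ValueError("dilation window does not fit inside the trial")


@dataclass(frozen=True)
class PupilEffectSpec:
    """Injected obtained-minus-unobtained dilation differences.

    The difference for a valence in a block is ``base_diff + vol_gain`` when
    that valence's schedule is volatile in the block, else ``base_diff``.
    Defaults emulate the study pattern: a larger baseline response difference
    and a larger volatility gain for losses than for wins.
    """

    base_diff_win: float = 0.25
    base_diff_loss: float = 0.45
    vol_gain_win: float = 0.15
    vol_gain_loss: float = 0.45

    def difference(self, valence: str, volatile: bool) -> float:
        if valence == "win":
            return self.base_diff_win + (self.vol_gain_win if volatile else 0.0)
        if valence == "loss":
            return self.base_diff_loss + (self.vol_gain_loss if volatile else 0.0)
        raise ValueError(f"unknown valence {valence!r}")


def block_types_for_order(order: BlockOrder) -> list[BlockType]:
    if BlockOrder(order) is BlockOrder.WIN_VOLATILE_FIRST:
        return [
            BlockType.BOTH_VOLATILE,
            BlockType.WIN_VOLATILE_LOSS_STABLE,
            BlockType.LOSS_VOLATILE_WIN_STABLE,
        ]
    return [
        BlockType.BOTH_VOLATILE,
        BlockType.LOSS_VOLATILE_WIN_STABLE,
        BlockType.WIN_VOLATILE_LOSS_STABLE,
    ]


def _earnings(choice: np.ndarray, win_side: np.ndarray, loss_side: np.ndarray) -> np.ndarray:
    won = choice == win_side
    lost = choice == loss_side
    return np.where(won & ~lost, WIN_PENCE, np.where(lost & ~won, LOSS_PENCE, 0))


def simulate_agent(
    variant: str,
    params: ModelParams,
    session_schedule: SessionSchedule,
    seed: int | np.random.SeedSequence,
    participant_id: str | int = 0,
) -> SessionData:
    """Sample one session of choices from a model variant.

    The task is full-information, so belief trajectories depend only on the
    schedule; choices are Bernoulli draws from the per-trial probability of
    choosing shape A.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for b, sched in enumerate(session_schedule.blocks, start=1):
        traj = model_variant_run(variant, sched, params)
        choice = np.where(
            rng.random(sched.n_trials) < traj.p_choose_A, "A", "B"
        )
        win_side = np.asarray(sched.win_side)
        loss_side = np.asarray(sched.loss_side)
        frames.append(
            pd.DataFrame(
                {
                    "block": b,
                    "trial": np.arange(1, sched.n_trials + 1),
                    "choice": choice,
                    "win_side": win_side,
                    "loss_side": loss_side,
                    "earnings_delta": _earnings(choice, win_side, loss_side),
                }
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    truth = {k: v for k, v in asdict(params).items() if v is not None}
    return SessionData(
        participant_id=participant_id,
        block_order=session_schedule.block_order,
        trials=trials,
        true_params=truth,
    )


def simulate_cohort(
    n: int,
    variant: str,
    param_sampler: Callable[[np.random.Generator], ModelParams],
    seed: int | np.random.SeedSequence,
) -> tuple[list[SessionData], pd.DataFrame]:
    """Simulate ``n`` agents with counterbalanced block order.

    Half the cohort (rounding down) completes the win-volatile block second;
    the rest complete the loss-volatile block second.  Per-participant
    generating parameters are drawn from ``param_sampler`` and returned as a
    ground-truth table alongside the sessions.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 participants")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(n)
    sessions: list[SessionData] = []
    truth_rows = []
    for i, child in enumerate(children):
        sched_seed, param_seed, choice_seed = child.spawn(3)
        order = (
            BlockOrder.WIN_VOLATILE_FIRST
            if i < n // 2
            else BlockOrder.LOSS_VOLATILE_FIRST
        )
        params = param_sampler(np.random.default_rng(param_seed))
        schedule = generate_session(order, sched_seed)
        sess = simulate_agent(
            variant, params, schedule, choice_seed, participant_id=i + 1
        )
        sessions.append(sess)
        truth_rows.append(
            {
                "participant": i + 1,
                "block_order": order.value,
                "model": variant,
                **sess.true_params,
            }
        )
    return sessions, pd.DataFrame(truth_rows)


def _dilation_kernel(gen: PupilGenParams) -> np.ndarray:
    """Gamma-shaped impulse response, peak normalised to 1."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(int(gen.kernel_duration_s * gen.sampling_rate)) / gen.sampling_rate
    k = gamma_dist.pdf(t, a=gen.kernel_shape, scale=gen.kernel_scale)
    return k / k.max()


def simulate_pupil(
    session: SessionData,
    gen: PupilGenParams = PupilGenParams(),
    effect: PupilEffectSpec = PupilEffectSpec(),
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw pupil trace plus event markers for one session.

    Returns ``(trace, markers)``: the trace has columns ``time_s, pupil,
    valid`` (valid=0 inside blinks); markers have one row per trial with the
    outcome-onset sample index and the obtained flag per valence.

    Win and loss dilations share the trial's single outcome-onset event; the
    per-valence amplitude is ``base_amp +/- difference/2`` for obtained /
    unobtained outcomes, where the difference is set by ``effect`` for the
    valence and the block's volatility role.
    """
    rng = np.random.default_rng(seed)
    fs = gen.sampling_rate
    spt = int(round(gen.trial_duration_s * fs))  # samples per trial
    n_trials = len(session.trials)
    n_samples = spt * n_trials
    btypes = block_types_for_order(session.block_order)

    kernel = _dilation_kernel(gen)
    t = np.arange(n_samples) / fs
    phase = rng.uniform(0, 2 * np.pi)
    trace = (
        gen.baseline_level
        + gen.drift_amplitude * np.sin(2 * np.pi * t / gen.drift_period_s + phase)
        + rng.normal(0.0, gen.noise_sd, n_samples)
    )

    markers = []
    for idx, row in enumerate(session.trials.itertuples(index=False)):
        btype = btypes[row.block - 1]
        win_vol = btype in (
            BlockType.BOTH_VOLATILE,
            BlockType.WIN_VOLATILE_LOSS_STABLE,
        )
        loss_vol = btype in (
            BlockType.BOTH_VOLATILE,
            BlockType.LOSS_VOLATILE_WIN_STABLE,
        )
        win_obtained = row.choice == row.win_side
        loss_obtained = row.choice == row.loss_side
        amp_w = gen.base_amp_win + (
            0.5 if win_obtained else -0.5
        ) * effect.difference("win", win_vol)
        amp_l = gen.base_amp_loss + (
            0.5 if loss_obtained else -0.5
        ) * effect.difference("loss", loss_vol)
        if amp_w < 0 or amp_l < 0:
            raise ValueError(
                "effect differences exceed base amplitudes: negative dilation"
            )
        onset = idx * spt + int(round(gen.outcome_onset_s * fs))
        stop = min(onset + kernel.size, n_samples)
        trace[onset:stop] += (amp_w + amp_l) * kernel[: stop - onset]
        markers.append(
            {
                "block": row.block,
                "trial": row.trial,
                "event_sample": onset,
                "win_obtained": int(win_obtained),
                "loss_obtained": int(loss_obtained),
            }
        )

    valid = np.ones(n_samples, dtype=int)
    n_blinks = rng.poisson(gen.blink_rate_hz * n_samples / fs)
    lo, hi = gen.blink_duration_range_s
    for _ in range(n_blinks):
        start = rng.integers(0, n_samples)
        dur = int(round(rng.uniform(lo, hi) * fs))
        valid[start : start + dur] = 0
    trace = np.where(valid == 1, trace, 0.0)

    trace_df = pd.DataFrame({"time_s": t, "pupil": trace, "valid": valid})
    return trace_df, pd.DataFrame(markers)
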