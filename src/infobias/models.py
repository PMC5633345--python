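"""The five behavioural models of choice in the dual-valence task.

All models map an outcome schedule and a parameter set to a per-trial
probability of choosing shape A, usable both generatively (sampling choices)
and for likelihood evaluation (scoring observed choices).

* ``m1`` -- two Rescorla-Wagner learners (one per valence) with separate
  learning rates ``alpha_win``/``alpha_loss`` and separate inverse
  temperatures ``beta_win``/``beta_loss``; this is the primary analysis model.
* ``m2`` -- model-free value learner: a single value for shape A updated from
  the joint (win - loss) outcome with one learning rate and one temperature.
* ``m3`` -- parameter-free hierarchical Bayesian (Behrens-style) learner per
  valence, with two temperatures entering only at the choice stage.
* ``m4`` -- as ``m1`` but with a single shared inverse temperature.
* ``m5`` -- as ``m4`` plus a risk parameter ``gamma`` warping both probability
  estimates before the softmax.

Belief-to-choice timing: the beliefs that drive the choice on trial ``i``
reflect outcomes up to trial ``i - 1``; both estimates start at 0.5 (``m2``'s
value starts at 0).  The task is full-information -- both outcome locations
are revealed whatever is chosen -- so every model updates on every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

from .schedule import OutcomeSchedule

__all__ = [
    "MODEL_VARIANTS",
    "FREE_PARAMS",
    "N_FREE_PARAMS",
    "ModelParams",
    "BeliefTrajectory",
    "rw_update",
    "rw_trajectory",
    "choice_prob_two_beta",
    "risk_transform",
    "model1_run",
    "model2_run",
    "model3_run",
    "model4_run",
    "model5_run",
    "model_variant_run",
]

MODEL_VARIANTS = ("m1", "m2", "m3", "m4", "m5")

#: Free parameters of each model variant, in canonical grid order.
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "m1": ("alpha_win", "alpha_loss", "beta_win", "beta_loss"),
    "m2": ("alpha_value", "beta_single"),
    "m3": ("beta_win", "beta_loss"),
    "m4": ("alpha_win", "alpha_loss", "beta_single"),
    "m5": ("alpha_win", "alpha_loss", "beta_single", "gamma"),
}

N_FREE_PARAMS = {v: len(p) for v, p in FREE_PARAMS.items()}

PROB_FLOOR = 1e-12  # floor applied to choice probabilities before logs


@dataclass
class ModelParams:
    """Parameter container; only the fields a variant uses may be set."""

    alpha_win: Optional[float] = None
    alpha_loss: Optional[float] = None
    beta_win: Optional[float] = None
    beta_loss: Optional[float] = None
    alpha_value: Optional[float] = None
    beta_single: Optional[float] = None
    gamma: Optional[float] = None

    def set_fields(self) -> set[str]:
        return {f.name for f in fields(self) if getattr(self, f.name) is not None}

    def require(self, variant: str) -> None:
        needed = set(FREE_PARAMS[variant])
        have = self.set_fields()
        if not needed <= have:
            raise ValueError(
                f"model {variant} requires parameters {sorted(needed)}, "
                f"got {sorted(have)}"
            )
        extra = have - needed
        if extra:
            raise ValueError(
                f"parameters {sorted(extra)} are not used by model {variant}"
            )
        for name in ("alpha_win", "alpha_loss", "alpha_value"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("beta_win", "beta_loss", "beta_single"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name}={v} must be >= 0")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError(f"gamma={self.gamma} must be > 0")

    @classmethod
    def for_variant(cls, variant: str, values) -> "ModelParams":
        """Build from an ordered sequence matching ``FREE_PARAMS[variant]``."""
        p = cls(**dict(zip(FREE_PARAMS[variant], values)))
        p.require(variant)
        return p


@dataclass
class BeliefTrajectory:
    """Per-trial latent estimates and choice probabilities for one block."""

    p_choose_A: np.ndarray
    r_win: Optional[np.ndarray] = None
    r_loss: Optional[np.ndarray] = None
    v_A: Optional[np.ndarray] = None

    @property
    def n_trials(self) -> int:
        return len(self.p_choose_A)

    def loglik(self, choices: np.ndarray, exclude_first: int = 0) -> float:
        """Bernoulli log-likelihood of observed choices ("A"/"B").

        ``exclude_first`` drops the first trials of the block from the sum
        (beliefs still reflect them; only their choice terms are omitted).
        """
        chose_A = np.asarray(choices) == "A"
        if len(chose_A) != self.n_trials:
            raise ValueError("choices do not align with the trajectory")
        p = np.where(chose_A, self.p_choose_A, 1.0 - self.p_choose_A)
        p = np.clip(p[exclude_first:], PROB_FLOOR, None)
        if p.size == 0:
            raise ValueError("no trials left after exclusion")
        return float(np.log(p).sum())


def rw_update(r: float, alpha: float, outcome_on_A: float) -> float:
    """One Rescorla-Wagner step: ``r + alpha * (outcome - r)``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"learning rate {alpha} outside [0, 1]")
    return r + alpha * (outcome_on_A - r)


def rw_trajectory(outcomes_on_A: np.ndarray, alpha: float, r0: float = 0.5) -> np.ndarray:
    """Belief series driven by an outcome indicator stream.

    Returns ``r[i]``, the estimate in force when trial ``i`` is played
    (``r[0] = r0``; ``r[i]`` incorporates outcomes ``0..i-1``).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"learning rate {alpha} outside [0, 1]")
    out = np.asarray(outcomes_on_A, dtype=float)
    r = np.empty(out.size)
    cur = r0
    for i, o in enumerate(out):
        r[i] = cur
        cur = cur + alpha * (o - cur)
    return r


def choice_prob_two_beta(
    r_win, r_loss, beta_win: float, beta_loss: float
) -> np.ndarray | float:
    """Softmax choice rule: logistic of ``beta_win*r_win - beta_loss*r_loss``."""
    from scipy.special import expit

    return expit(beta_win * np.asarray(r_win) - beta_loss * np.asarray(r_loss))


def risk_transform(r, gamma: float):
    """Non-linear probability warp ``2**(-(-log2 r)**gamma)``.

    Identity at ``gamma = 1`` and at ``r = 0.5``; ``gamma > 1`` deflates small
    probabilities, ``gamma < 1`` inflates them.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("risk_transform requires r in (0, 1]")
    if gamma == 1.0:  # exact identity; avoids log/exp round-trip error
        return r.copy()
    return 2.0 ** (-((-np.log2(r)) ** gamma))


def model1_run(schedule: OutcomeSchedule, params: ModelParams) -> BeliefTrajectory:
    """Two independent RW learners with valence-specific temperatures."""
    params.require("m1")
    r_win = rw_trajectory(schedule.win_on_A, params.alpha_win)
    r_loss = rw_trajectory(schedule.loss_on_A, params.alpha_loss)
    p = choice_prob_two_beta(r_win, r_loss, params.beta_win, params.beta_loss)
    return BeliefTrajectory(p_choose_A=p, r_win=r_win, r_loss=r_loss)


def model2_run(schedule: OutcomeSchedule, params: ModelParams) -> BeliefTrajectory:
    """Model-free value learner on the joint (win - loss) outcome of shape A.

    Both outcome locations are shown every trial, so the value of A is updated
    every trial and ``v_B = -v_A`` exactly; the softmax acts on
    ``beta_single * (v_A - v_B) = 2 * beta_single * v_A``.
    """
    from scipy.special import expit

    params.require("m2")
    out = schedule.win_on_A - schedule.loss_on_A  # in {-1, 0, 1}
    v = np.empty(schedule.n_trials)
    cur = 0.0
    for i, o in enumerate(out):
        v[i] = cur
        cur = cur + params.alpha_value * (o - cur)
    p = expit(params.beta_single * 2.0 * v)
    return BeliefTrajectory(p_choose_A=p, v_A=v)


def model3_run(
    schedule: OutcomeSchedule, params: ModelParams | None = None
) -> BeliefTrajectory:
    """Parameter-free Bayesian volatility learner per valence.

    The learner itself has no free parameters; if ``params`` carries
    ``beta_win``/``beta_loss`` the choice probabilities are computed, else
    they default to 1 (the posterior-mean trajectories are the point).
    """
    from .bayes_learner import posterior_mean_trajectory

    r_win = posterior_mean_trajectory(schedule.win_on_A)
    r_loss = posterior_mean_trajectory(schedule.loss_on_A)
    if params is None:
        bw = bl = 1.0
    else:
        params.require("m3")
        bw, bl = params.beta_win, params.beta_loss
    p = choice_prob_two_beta(r_win, r_loss, bw, bl)
    return BeliefTrajectory(p_choose_A=p, r_win=r_win, r_loss=r_loss)


def model4_run(schedule: OutcomeSchedule, params: ModelParams) -> BeliefTrajectory:
    """As model 1, with a single shared inverse temperature."""
    params.require("m4")
    r_win = rw_trajectory(schedule.win_on_A, params.alpha_win)
    r_loss = rw_trajectory(schedule.loss_on_A, params.alpha_loss)
    p = choice_prob_two_beta(r_win, r_loss, params.beta_single, params.beta_single)
    return BeliefTrajectory(p_choose_A=p, r_win=r_win, r_loss=r_loss)


def model5_run(schedule: OutcomeSchedule, params: ModelParams) -> BeliefTrajectory:
    """Model 4 with the risk warp applied to both estimates pre-softmax."""
    params.require("m5")
    r_win = rw_trajectory(schedule.win_on_A, params.alpha_win)
    r_loss = rw_trajectory(schedule.loss_on_A, params.alpha_loss)
    rw_t = risk_transform(r_win, params.gamma)
    rl_t = risk_transform(r_loss, params.gamma)
    p = choice_prob_two_beta(rw_t, rl_t, params.beta_single, params.beta_single)
    return BeliefTrajectory(p_choose_A=p, r_win=r_win, r_loss=r_loss)


_RUNNERS = {
    "m1": model1_run,
    "m2": model2_run,
    "m3": model3_run,
    "m4": model4_run,
    "m5": model5_run,
}


def model_variant_run(
    variant: str, schedule: OutcomeSchedule, params: ModelParams
) -> BeliefTrajectory:
    """Dispatch to the named model variant, checking the parameter set."""
    if variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    if variant == "m3":
        params.require("m3")
        return model3_run(schedule, params)
    return _RUNNERS[variant](schedule, params)
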