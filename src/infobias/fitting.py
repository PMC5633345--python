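"""Grid-posterior parameter estimation and BIC model comparison.

Parameters are estimated per participant and per block by evaluating the
Bernoulli choice likelihood of a model variant over a dense parameter grid,
normalising (with a uniform prior by default) to the full joint posterior, and
reporting the expectation of each parameter under its marginal posterior.
Choice data from the first 10 trials of each block is excluded from the
likelihood (beliefs still update through those trials).

Model comparison sums, per participant, the per-block BIC

    BIC_block = k * ln(n_block) - 2 * logLik_block

over the three task blocks, where ``k`` is the variant's free-parameter count,
``n_block`` the number of likelihood-contributing trials and the
log-likelihood is evaluated at the posterior-expected parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit, logsumexp

from .models import (
    FREE_PARAMS,
    N_FREE_PARAMS,
    ModelParams,
    model_variant_run,
    risk_transform,
    rw_trajectory,
)
from .schedule import OutcomeSchedule

__all__ = [
    "ParamGrid",
    "BlockFit",
    "ModelFit",
    "default_grid",
    "block_loglik",
    "loglik_grid",
    "grid_posterior",
    "marginal_expectation",
    "fit_block",
    "fit_participant",
    "transform_params",
    "compare_models",
    "schedule_from_trials",
]

_LOG_FLOOR = np.log(1e-12)
EXCLUDE_FIRST_DEFAULT = 10

try:  # JIT likelihood kernels; the numpy path below remains the reference.
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

if _HAVE_NUMBA:

    @_njit(cache=True, fastmath=True)
    def _ll_cross_nb(A, B):  # pragma: no cover - compiled
        """ll[p, q] = sum_t max(-softplus(-(A[p,t]-B[q,t])), log floor).

        Uses softplus(-(A-B)) = log1p(e^{-A} e^{B}) with the exponentials
        hoisted out of the pairwise loop; |A|,|B| <= beta_max keeps the
        products finite in float64.
        """
        P, T = A.shape
        Q = B.shape[0]
        cap = 27.631021115928547  # -log(1e-12)
        EA = np.exp(-A)
        EB = np.exp(B)
        out = np.empty((P, Q))
        for p in range(P):
            for q in range(Q):
                s = 0.0
                for t in range(T):
                    sp = np.log1p(EA[p, t] * EB[q, t])
                    s -= sp if sp < cap else cap
                out[p, q] = s
        return out

    @_njit(cache=True, fastmath=True)
    def _ll_shared_beta_nb(Rw, Rl, betas, sign):  # pragma: no cover
        """ll[a, c, i] for x_t = betas[i]*(Rw[a,t]-Rl[c,t]), choice sign."""
        Aw, T = Rw.shape
        Al = Rl.shape[0]
        nb = betas.size
        cap = 27.631021115928547
        EW = np.empty((nb, Aw, T))
        EL = np.empty((nb, Al, T))
        for i in range(nb):
            for t in range(T):
                for a in range(Aw):
                    EW[i, a, t] = np.exp(-sign[t] * betas[i] * Rw[a, t])
                for c in range(Al):
                    EL[i, c, t] = np.exp(sign[t] * betas[i] * Rl[c, t])
        out = np.empty((Aw, Al, nb))
        for a in range(Aw):
            for c in range(Al):
                for i in range(nb):
                    s = 0.0
                    for t in range(T):
                        sp = np.log1p(EW[i, a, t] * EL[i, c, t])
                        s -= sp if sp < cap else cap
                    out[a, c, i] = s
        return out


@dataclass(frozen=True)
class ParamGrid:
    """Ordered per-parameter value lists plus an optional joint prior."""

    names: tuple[str, ...]
    values: tuple[np.ndarray, ...]
    prior: np.ndarray | None = None  # joint weights over the grid; None=uniform

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values must align")
        for name, v in zip(self.names, self.values):
            v = np.asarray(v, dtype=float)
            if v.ndim != 1 or not np.all(np.diff(v) > 0):
                raise ValueError(f"grid for {name} must be strictly increasing")
        if self.prior is not None:
            p = np.asarray(self.prior, dtype=float)
            if p.shape != self.shape:
                raise ValueError("prior shape does not match the grid")
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("prior weights must be non-negative, sum to 1")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.values)

    def axis(self, name: str) -> int:
        return self.names.index(name)

    def log_prior(self) -> np.ndarray:
        if self.prior is None:
            return np.full(self.shape, -np.log(np.prod(self.shape)))
        with np.errstate(divide="ignore"):
            return np.log(self.prior)


def _lr_grid(n: int) -> np.ndarray:
    return np.linspace(0.01, 0.99, n)


def _beta_grid(n: int) -> np.ndarray:
    return np.geomspace(0.1, 30.0, n)


def _gamma_grid(n: int) -> np.ndarray:
    return np.geomspace(0.2, 5.0, n)


def default_grid(variant: str, reduced: bool = False) -> ParamGrid:
    """Default estimation grid for a variant.

    Learning rates: 50 equally spaced points on [0.01, 0.99]; inverse
    temperatures: 40 log-spaced on [0.1, 30]; gamma: 20 log-spaced on
    [0.2, 5]; uniform prior.  ``reduced=True`` coarsens to 30 learning-rate
    and 20 temperature points for large model-comparison batteries.
    """
    n_lr, n_beta = (30, 20) if reduced else (50, 40)
    pools = {
        "alpha_win": _lr_grid(n_lr),
        "alpha_loss": _lr_grid(n_lr),
        "alpha_value": _lr_grid(n_lr),
        "beta_win": _beta_grid(n_beta),
        "beta_loss": _beta_grid(n_beta),
        "beta_single": _beta_grid(n_beta),
        "gamma": _gamma_grid(20),
    }
    names = FREE_PARAMS[variant]
    return ParamGrid(names=names, values=tuple(pools[n] for n in names))


def schedule_from_trials(block_df: pd.DataFrame) -> OutcomeSchedule:
    """Realised-outcome schedule from a trial table (one block).

    The generating probability trajectories are unknown at fit time and are
    filled with NaN; likelihood evaluation uses only the realised sides.
    """
    n = len(block_df)
    return OutcomeSchedule(
        p_win_A=np.full(n, np.nan),
        p_loss_A=np.full(n, np.nan),
        win_side=block_df["win_side"].to_numpy(),
        loss_side=block_df["loss_side"].to_numpy(),
    )


def block_loglik(
    variant: str,
    schedule: OutcomeSchedule,
    choices: np.ndarray,
    params: ModelParams,
    exclude_first: int = EXCLUDE_FIRST_DEFAULT,
) -> float:
    """Choice log-likelihood of one block at a single parameter point."""
    if len(choices) != schedule.n_trials:
        raise ValueError("choices do not align with the schedule")
    if schedule.n_trials <= exclude_first:
        raise ValueError("no trials left after excluding the first ones")
    traj = model_variant_run(variant, schedule, params)
    return traj.loglik(np.asarray(choices), exclude_first=exclude_first)


def _rw_grid(outcomes: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """RW belief series for every learning rate at once; shape (n_alpha, T)."""
    out = np.asarray(outcomes, dtype=float)
    r = np.empty((alphas.size, out.size))
    cur = np.full(alphas.size, 0.5)
    for i, o in enumerate(out):
        r[:, i] = cur
        cur = cur + alphas * (o - cur)
    return r


def _ll_from_logits(x: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Sum over the trailing trial axis of log P(choice) given choice logits.

    ``x`` is the logit of choosing A per grid point and trial; ``sign`` is +1
    where A was chosen, -1 otherwise.  Uses log(sigmoid(s*x)) =
    -log1p(exp(-s*x)) with the 1e-12 probability floor.
    """
    logp = -np.logaddexp(0.0, -sign * x)
    return np.maximum(logp, _LOG_FLOOR).sum(axis=-1)


def loglik_grid(
    variant: str,
    schedule: OutcomeSchedule,
    choices: np.ndarray,
    grid: ParamGrid,
    exclude_first: int = EXCLUDE_FIRST_DEFAULT,
    use_numba: bool | None = None,
) -> np.ndarray:
    """Log-likelihood at every grid point; shape ``grid.shape``.

    Vectorised per variant: belief trajectories depend only on learning-rate
    axes and are shared across all temperature (and risk) values, so they are
    computed once per learning rate and broadcast, chunking over temperature
    axes to bound memory.  Compiled kernels are used for the large m1/m4/m5
    grids when numba is available (``use_numba=False`` forces the pure-numpy
    reference path; both paths implement the same floored Bernoulli
    log-likelihood).
    """
    if use_numba is None:
        use_numba = _HAVE_NUMBA
    if tuple(grid.names) != FREE_PARAMS[variant]:
        raise ValueError(
            f"grid names {grid.names} do not match {FREE_PARAMS[variant]}"
        )
    chose_A = np.asarray(choices) == "A"
    if chose_A.size != schedule.n_trials:
        raise ValueError("choices do not align with the schedule")
    sign = np.where(chose_A, 1.0, -1.0)[exclude_first:]
    if sign.size == 0:
        raise ValueError("no trials left after excluding the first ones")
    sl = slice(exclude_first, None)

    if variant == "m1":
        aw, al, bw, bl = grid.values
        Rw = _rw_grid(schedule.win_on_A, aw)[:, sl]
        Rl = _rw_grid(schedule.loss_on_A, al)[:, sl]
        if use_numba:
            # sign folded into both halves of the choice logit.
            A = (sign * bw[:, None, None] * Rw[None, :, :]).reshape(-1, sign.size)
            B = (sign * bl[:, None, None] * Rl[None, :, :]).reshape(-1, sign.size)
            ll = _ll_cross_nb(A, B)  # (Bw*Aw, Bl*Al)
            return (
                ll.reshape(bw.size, aw.size, bl.size, al.size)
                .transpose(1, 3, 0, 2)
                .copy()
            )
        ll = np.empty(grid.shape)
        bwRw = bw[:, None, None] * Rw[None, :, :]  # (Bw, Aw, T)
        for j, b in enumerate(bl):
            x = bwRw[:, :, None, :] - b * Rl[None, None, :, :]
            ll[:, :, :, j] = _ll_from_logits(x, sign).transpose(1, 2, 0)
        return ll

    if variant == "m4":
        aw, al, bs = grid.values
        Rw = _rw_grid(schedule.win_on_A, aw)[:, sl]
        Rl = _rw_grid(schedule.loss_on_A, al)[:, sl]
        if use_numba:
            return _ll_shared_beta_nb(Rw, Rl, bs, sign)
        diff = Rw[:, None, :] - Rl[None, :, :]  # (Aw, Al, T)
        ll = np.empty(grid.shape)
        for j, b in enumerate(bs):
            ll[:, :, j] = _ll_from_logits(b * diff, sign)
        return ll

    if variant == "m5":
        aw, al, bs, gam = grid.values
        Rw = _rw_grid(schedule.win_on_A, aw)[:, sl]
        Rl = _rw_grid(schedule.loss_on_A, al)[:, sl]
        ll = np.empty(grid.shape)
        for g, gv in enumerate(gam):
            Rw_t, Rl_t = risk_transform(Rw, gv), risk_transform(Rl, gv)
            if use_numba:
                ll[:, :, :, g] = _ll_shared_beta_nb(Rw_t, Rl_t, bs, sign)
                continue
            diff = Rw_t[:, None, :] - Rl_t[None, :, :]
            for j, b in enumerate(bs):
                ll[:, :, j, g] = _ll_from_logits(b * diff, sign)
        return ll

    if variant == "m2":
        av, bs = grid.values
        out = schedule.win_on_A - schedule.loss_on_A
        V = np.empty((av.size, out.size))
        cur = np.zeros(av.size)
        for i, o in enumerate(out):
            V[:, i] = cur
            cur = cur + av * (o - cur)
        V = V[:, sl]
        x = 2.0 * bs[:, None, None] * V[None, :, :]  # (B, Av, T)
        return _ll_from_logits(x, sign).T

    if variant == "m3":
        from .bayes_learner import posterior_mean_trajectory

        bw, bl = grid.values
        rw = posterior_mean_trajectory(schedule.win_on_A)[sl]
        rl = posterior_mean_trajectory(schedule.loss_on_A)[sl]
        x = bw[:, None, None] * rw - bl[None, :, None] * rl
        return _ll_from_logits(x, sign)

    raise ValueError(f"unknown model variant {variant!r}")


def grid_posterior(
    variant: str,
    schedule: OutcomeSchedule,
    choices: np.ndarray,
    grid: ParamGrid,
    exclude_first: int = EXCLUDE_FIRST_DEFAULT,
) -> np.ndarray:
    """Normalised joint posterior over the grid (log-space computation)."""
    if exclude_first >= schedule.n_trials:
        # No likelihood-contributing trials: posterior equals the prior.
        lp = grid.log_prior()
        return np.exp(lp - logsumexp(lp))
    ll = loglik_grid(variant, schedule, choices, grid, exclude_first)
    lp = ll + grid.log_prior()
    norm = logsumexp(lp)
    if not np.isfinite(norm):
        raise FloatingPointError(
            "posterior mass underflowed on the whole grid; likelihood is "
            "degenerate for these choices"
        )
    post = np.exp(lp - norm)
    return post / post.sum()


def marginal_expectation(
    posterior: np.ndarray, grid: ParamGrid, name: str
) -> float:
    """Posterior expectation of one parameter from its marginal."""
    ax = grid.axis(name)
    other = tuple(i for i in range(posterior.ndim) if i != ax)
    marg = posterior.sum(axis=other)
    return float(marg @ grid.values[ax])


@dataclass
class BlockFit:
    """Posterior-expected parameters and fit quality for one block."""

    params: dict[str, float]
    loglik: float
    n_trials: int  # likelihood-contributing trials
    posterior: np.ndarray | None = None

    def bic(self, k: int) -> float:
        return k * np.log(self.n_trials) - 2.0 * self.loglik


@dataclass
class ModelFit:
    """Per-block grid-posterior fit of one variant to one session."""

    variant: str
    blocks: list[BlockFit]
    participant: str | int | None = None

    @property
    def k(self) -> int:
        return N_FREE_PARAMS[self.variant]

    @property
    def loglik_total(self) -> float:
        return sum(b.loglik for b in self.blocks)

    @property
    def bic_total(self) -> float:
        """Summed BIC across blocks: sum of k*ln(n_block) - 2*logLik_block."""
        return sum(b.bic(self.k) for b in self.blocks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.blocks, start=1):
            row = {
                "participant": self.participant,
                "model": self.variant,
                "block": i,
                **{
                    name: b.params.get(name, np.nan)
                    for name in (
                        "alpha_win",
                        "alpha_loss",
                        "beta_win",
                        "beta_loss",
                        "alpha_value",
                        "beta_single",
                        "gamma",
                    )
                },
                "loglik": b.loglik,
                "n_trials": b.n_trials,
                "bic": b.bic(self.k),
            }
            rows.append(row)
        return pd.DataFrame(rows)


def fit_block(
    variant: str,
    schedule: OutcomeSchedule,
    choices: np.ndarray,
    grid: ParamGrid | None = None,
    exclude_first: int = EXCLUDE_FIRST_DEFAULT,
    keep_posterior: bool = False,
) -> BlockFit:
    """Grid posterior, marginal expectations and log-likelihood for a block."""
    if grid is None:
        grid = default_grid(variant)
    post = grid_posterior(variant, schedule, choices, grid, exclude_first)
    expected = {
        name: marginal_expectation(post, grid, name) for name in grid.names
    }
    params = ModelParams(**expected)
    ll = block_loglik(variant, schedule, choices, params, exclude_first)
    return BlockFit(
        params=expected,
        loglik=ll,
        n_trials=schedule.n_trials - exclude_first,
        posterior=post if keep_posterior else None,
    )


def fit_participant(
    variant: str,
    trials: pd.DataFrame,
    grid: ParamGrid | None = None,
    exclude_first: int = EXCLUDE_FIRST_DEFAULT,
    participant: str | int | None = None,
) -> ModelFit:
    """Independent per-block fits for one participant's trial table.

    ``trials`` needs columns ``block, trial, choice, win_side, loss_side``
    with three blocks present.
    """
    if grid is None:
        grid = default_grid(variant)
    block_ids = sorted(trials["block"].unique())
    if len(block_ids) != 3:
        raise ValueError(f"expected 3 blocks, found {block_ids}")
    blocks = []
    for b in block_ids:
        df = trials[trials["block"] == b].sort_values("trial")
        sched = schedule_from_trials(df)
        blocks.append(
            fit_block(
                variant, sched, df["choice"].to_numpy(), grid, exclude_first
            )
        )
    return ModelFit(variant=variant, blocks=blocks, participant=participant)


_LR_NAMES = ("alpha_win", "alpha_loss", "alpha_value")
_POSITIVE_NAMES = ("beta_win", "beta_loss", "beta_single", "gamma")


def transform_params(params: Mapping[str, float], clamp: float = 1e-6) -> dict[str, float]:
    """Map parameters onto the real line for group statistics.

    Learning rates (0,1) go through the logit; inverse temperatures (and the
    risk parameter) through the natural log.  Values at or beyond the domain
    boundary are clamped at ``clamp`` with a warning.
    """
    out: dict[str, float] = {}
    for name, v in params.items():
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out[name] = np.nan
        elif name in _LR_NAMES:
            if not 0.0 < v < 1.0:
                warnings.warn(
                    f"{name}={v} at the boundary of (0,1); clamping",
                    RuntimeWarning,
                    stacklevel=2,
                )
                v = np.clip(v, clamp, 1.0 - clamp)
            out[name] = float(logit(v))
        elif name in _POSITIVE_NAMES:
            if v <= 0.0:
                warnings.warn(
                    f"{name}={v} at the boundary of (0,inf); clamping",
                    RuntimeWarning,
                    stacklevel=2,
                )
                v = clamp
            out[name] = float(np.log(v))
        else:
            out[name] = float(v)
    return out


def compare_models(
    fits: Mapping[str, Sequence[ModelFit]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-level BIC comparison across variants.

    ``fits`` maps variant -> one ModelFit per participant (same participants,
    same order, under every variant).  Returns (summary, per_participant):
    summary has mean and SEM of the summed BIC per variant; per_participant
    has each participant's BIC per variant and the best (argmin) variant, with
    exact ties reported as ``"tie"``.
    """
    variants = list(fits)
    n_parts = {v: len(fits[v]) for v in variants}
    if len(set(n_parts.values())) != 1:
        raise ValueError(f"unequal cohort sizes across variants: {n_parts}")
    bic = pd.DataFrame(
        {v: [f.bic_total for f in fits[v]] for v in variants},
        index=[f.participant for f in fits[variants[0]]],
    )
    summary = pd.DataFrame(
        {
            "mean_bic": bic.mean(),
            "sem_bic": bic.std(ddof=1) / np.sqrt(len(bic)),
        }
    )
    mins = bic.min(axis=1)
    is_min = bic.eq(mins, axis=0)
    best = bic.idxmin(axis=1).where(is_min.sum(axis=1) == 1, "tie")
    per_part = bic.copy()
    per_part["best_model"] = best
    return summary, per_part
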