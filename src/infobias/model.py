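"""Model/Results front end for valence-specific learning-rate estimation.

`ValenceLearningModel` wraps a participant's trial table and a model variant;
``fit()`` runs the per-block grid posterior and returns a
`ValenceLearningResults` carrying posterior-expected parameters, per-block
log-likelihoods, BIC and posterior-sd uncertainties, with a ``summary()``
table.  Simulation (``model.simulate``) and posterior plots
(``results.plot_posterior``) hang off the two objects.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import fitting
from .fitting import ModelFit, ParamGrid, default_grid, marginal_expectation
from .models import FREE_PARAMS, ModelParams
from .schedule import SessionSchedule

__all__ = ["ValenceLearningModel", "ValenceLearningResults"]


class ValenceLearningModel:
    """A behavioural model variant bound to one participant's choice data.

    Parameters
    ----------
    trials
        Trial table with columns ``block, trial, choice, win_side,
        loss_side`` (choice and sides coded ``A``/``B``), three blocks.
    variant
        One of ``m1`` (valence-specific learning rates and temperatures, the
        primary model), ``m2`` (model-free value learner), ``m3``
        (parameter-free Bayesian learner), ``m4`` (single temperature),
        ``m5`` (single temperature plus risk warp).
    grid
        Estimation grid; defaults to :func:`infobias.fitting.default_grid`.
    exclude_first
        Leading trials per block whose choices are excluded from the
        likelihood (belief updating still runs through them).
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        variant: str = "m1",
        grid: Optional[ParamGrid] = None,
        exclude_first: int = fitting.EXCLUDE_FIRST_DEFAULT,
    ) -> None:
        required = {"block", "trial", "choice", "win_side", "loss_side"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trial table is missing columns {sorted(missing)}")
        if variant not in FREE_PARAMS:
            raise ValueError(f"unknown model variant {variant!r}")
        self.trials = trials.sort_values(["block", "trial"]).reset_index(drop=True)
        self.variant = variant
        self.grid = grid if grid is not None else default_grid(variant)
        self.exclude_first = exclude_first

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ValenceLearningModel":
        return cls(pd.read_csv(path), **kwargs)

    # -- estimation --------------------------------------------------------

    def loglike(self, params: ModelParams) -> float:
        """Total choice log-likelihood across blocks at one parameter point."""
        total = 0.0
        for _, df in self.trials.groupby("block"):
            sched = fitting.schedule_from_trials(df)
            total += fitting.block_loglik(
                self.variant, sched, df["choice"].to_numpy(), params,
                self.exclude_first,
            )
        return total

    def fit(self, keep_posteriors: bool = True) -> "ValenceLearningResults":
        """Per-block grid posterior and marginal expectations."""
        block_ids = sorted(self.trials["block"].unique())
        blocks = []
        for b in block_ids:
            df = self.trials[self.trials["block"] == b].sort_values("trial")
            sched = fitting.schedule_from_trials(df)
            blocks.append(
                fitting.fit_block(
                    self.variant,
                    sched,
                    df["choice"].to_numpy(),
                    self.grid,
                    self.exclude_first,
                    keep_posterior=keep_posteriors,
                )
            )
        mf = ModelFit(variant=self.variant, blocks=blocks)
        return ValenceLearningResults(self, mf, block_ids)

    # -- simulation --------------------------------------------------------

    def simulate(
        self,
        params: ModelParams,
        session_schedule: SessionSchedule,
        seed: int | np.random.SeedSequence = 0,
        participant_id: str | int = 0,
    ):
        """Generate a synthetic session from this variant at ``params``."""
        from .agents import simulate_agent

        return simulate_agent(
            self.variant, params, session_schedule, seed,
            participant_id=participant_id,
        )


class ValenceLearningResults:
    """Fit results: posterior-expected parameters, uncertainty, BIC."""

    def __init__(
        self, model: ValenceLearningModel, fit: ModelFit, block_ids
    ) -> None:
        self.model = model
        self._fit = fit
        self.block_ids = list(block_ids)

    @property
    def variant(self) -> str:
        return self._fit.variant

    @property
    def params(self) -> pd.DataFrame:
        """Posterior-expected parameters, one row per block."""
        return pd.DataFrame(
            [b.params for b in self._fit.blocks], index=self.block_ids
        ).rename_axis("block")

    @property
    def bse(self) -> pd.DataFrame:
        """Posterior standard deviation of each parameter per block."""
        rows = []
        for b in self._fit.blocks:
            if b.posterior is None:
                rows.append({k: np.nan for k in b.params})
                continue
            row = {}
            for name in self.model.grid.names:
                ax = self.model.grid.axis(name)
                other = tuple(
                    i for i in range(b.posterior.ndim) if i != ax
                )
                marg = b.posterior.sum(axis=other)
                vals = self.model.grid.values[ax]
                mean = marg @ vals
                row[name] = float(np.sqrt(marg @ (vals - mean) ** 2))
            rows.append(row)
        return pd.DataFrame(rows, index=self.block_ids).rename_axis("block")

    @property
    def loglik(self) -> pd.Series:
        return pd.Series(
            [b.loglik for b in self._fit.blocks],
            index=self.block_ids,
            name="loglik",
        ).rename_axis("block")

    @property
    def bic(self) -> float:
        """BIC summed over blocks at the posterior-expected parameters."""
        return self._fit.bic_total

    @property
    def model_fit(self) -> ModelFit:
        return self._fit

    def transformed_params(self) -> pd.DataFrame:
        """Parameters mapped to the real line (logit / log) per block."""
        return pd.DataFrame(
            [fitting.transform_params(b.params) for b in self._fit.blocks],
            index=self.block_ids,
        ).rename_axis("block")

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels style."""
        lines = [
            "Valence-specific learning model fit",
            "=" * 60,
            f"Variant: {self.variant}   free parameters/block: {self._fit.k}",
            f"Trials/block in likelihood: "
            f"{[b.n_trials for b in self._fit.blocks]}",
            f"Log-likelihood (total): {self._fit.loglik_total:.3f}",
            f"BIC (summed over blocks): {self.bic:.3f}",
            "-" * 60,
        ]
        p = self.params
        s = self.bse
        header = f"{'block':>6} " + "".join(
            f"{name:>12}" for name in self.model.grid.names
        )
        lines.append(header)
        for blk in self.block_ids:
            lines.append(
                f"{blk:>6} "
                + "".join(f"{p.loc[blk, n]:>12.4f}" for n in self.model.grid.names)
            )
            if not np.isnan(s.loc[blk]).all():
                lines.append(
                    f"{'(sd)':>6} "
                    + "".join(
                        f"{s.loc[blk, n]:>12.4f}" for n in self.model.grid.names
                    )
                )
        lines.append("=" * 60)
        return "\n".join(lines)

    def plot_posterior(self, block, ax=None):
        """Marginal posterior of every parameter for one block."""
        import matplotlib.pyplot as plt

        i = self.block_ids.index(block)
        post = self._fit.blocks[i].posterior
        if post is None:
            raise ValueError("posteriors were not kept; refit with keep_posteriors=True")
        names = self.model.grid.names
        if ax is None:
            _, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 2.5))
        else:
            axes = np.atleast_1d(ax)
        for a, name in zip(np.ravel(axes), names):
            axn = self.model.grid.axis(name)
            other = tuple(j for j in range(post.ndim) if j != axn)
            a.plot(self.model.grid.values[axn], post.sum(axis=other))
            a.set_xlabel(name)
        return axes

    def plot_beliefs(self, block, ax=None):
        """Belief trajectories implied by the expected parameters."""
        import matplotlib.pyplot as plt
        from .models import model_variant_run

        i = self.block_ids.index(block)
        df = self.model.trials[self.model.trials["block"] == block]
        sched = fitting.schedule_from_trials(df)
        params = ModelParams(**self._fit.blocks[i].params)
        traj = model_variant_run(self.variant, sched, params)
        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(1, sched.n_trials + 1)
        if traj.r_win is not None:
            ax.plot(t, traj.r_win, label="r_win", color="tab:green")
            ax.plot(t, traj.r_loss, label="r_loss", color="tab:red")
        if traj.v_A is not None:
            ax.plot(t, traj.v_A, label="v_A", color="tab:blue")
        ax.plot(t, traj.p_choose_A, label="P(choose A)", color="k", alpha=0.5)
        ax.set_xlabel("trial")
        ax.legend()
        return ax
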