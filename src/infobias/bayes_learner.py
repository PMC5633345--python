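"""Grid-based hierarchical Bayesian learner for binary outcome streams.

Tracks a latent outcome probability ``r`` that drifts at a rate set by a
latent log-volatility ``v``, which itself performs a random walk whose step
variance is ``exp(k)``; ``k`` is a static hyperparameter learned jointly.
The generative model per trial is

    v(i+1) | v(i), k  ~  Normal(v(i), exp(k))
    r(i+1) | r(i), v(i+1)  ~  Beta with mean r(i) and spread governed by
                              exp(v(i+1))
    y(i)   | r(i)  ~  Bernoulli(r(i))

and inference is exact on a fixed 3-D grid: the joint posterior over
``(r, v, k)`` is propagated through the transition kernels and multiplied by
the Bernoulli likelihood after every observation.  The learner has no free
parameters; grids and priors are fixed.

The beta drift kernel uses concentration ``nu = 1/exp(v)``: high volatility
(large ``v``) gives a diffuse kernel and fast tracking, low volatility an
almost-degenerate kernel and slow tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import norm

__all__ = ["BayesianLearnerGrid", "run_filter", "posterior_mean_trajectory"]


@dataclass(frozen=True)
class BayesianLearnerGrid:
    """Grid resolution and ranges for the volatility filter."""

    n_r: int = 50
    n_v: int = 30
    n_k: int = 15
    r_range: tuple[float, float] = (0.01, 0.99)
    v_range: tuple[float, float] = (-8.0, 2.0)
    k_range: tuple[float, float] = (-4.0, 2.0)

    @property
    def r(self) -> np.ndarray:
        return np.linspace(*self.r_range, self.n_r)

    @property
    def v(self) -> np.ndarray:
        return np.linspace(*self.v_range, self.n_v)

    @property
    def k(self) -> np.ndarray:
        return np.linspace(*self.k_range, self.n_k)


@lru_cache(maxsize=4)
def _kernels(grid: BayesianLearnerGrid):
    """Precompute discretised transition kernels for a grid."""
    r, v, k = grid.r, grid.v, grid.k
    # v drift: T_v[k, v, v'] = P(v' | v, k), rows normalised over v'.
    sd = np.sqrt(np.exp(k))[:, None, None]
    T_v = norm.pdf(v[None, None, :], loc=v[None, :, None], scale=sd)
    T_v /= T_v.sum(axis=2, keepdims=True)
    # r drift: T_r[v', r, r'] = P(r' | r, v'), beta kernel with mean r and
    # concentration nu = exp(-v'); rows normalised over r'.
    nu = np.exp(-v)[:, None, None]
    a = r[None, :, None] * nu
    b = (1.0 - r[None, :, None]) * nu
    logpdf = (
        (a - 1.0) * np.log(r[None, None, :])
        + (b - 1.0) * np.log1p(-r[None, None, :])
    )
    logpdf -= logpdf.max(axis=2, keepdims=True)
    T_r = np.exp(logpdf)
    T_r /= T_r.sum(axis=2, keepdims=True)
    return T_r, T_v


def run_filter(
    outcomes: np.ndarray, grid: BayesianLearnerGrid = BayesianLearnerGrid()
) -> dict[str, np.ndarray]:
    """Filter a 0/1 outcome stream; return predictive summaries per trial.

    Returns arrays aligned with trials: ``r_mean[i]`` (and ``v_mean[i]``) are
    the posterior means *before* observing outcome ``i`` — i.e. the estimates
    a learner would act on when playing trial ``i`` — plus the final joint
    posterior and an edge-mass diagnostic flag.
    """
    T_r, T_v = _kernels(grid)
    r, v = grid.r, grid.v
    y = np.asarray(outcomes, dtype=float)
    n = y.size
    # Uniform joint prior over (r, v, k).
    p = np.full((grid.n_r, grid.n_v, grid.n_k), 1.0)
    p /= p.sum()
    r_mean = np.empty(n)
    v_mean = np.empty(n)
    edge_mass = 0.0
    for i in range(n):
        r_marg = p.sum(axis=(1, 2))
        v_marg = p.sum(axis=(0, 2))
        r_mean[i] = float(r_marg @ r)
        v_mean[i] = float(v_marg @ v)
        edge_mass = max(edge_mass, r_marg[0] + r_marg[-1])
        # Observe outcome i.
        like = np.where(y[i] > 0.5, r, 1.0 - r)[:, None, None]
        p = p * like
        p /= p.sum()
        # Propagate to trial i+1: v drifts given k, then r drifts given v'.
        p = np.einsum("rvk,kvw->rwk", p, T_v)
        p = np.einsum("rvk,vrs->svk", p, T_r)
        p /= p.sum()
    if edge_mass > 0.5:
        import warnings

        warnings.warn(
            "posterior mass concentrating on the r-grid edges; "
            "consider a finer or wider grid",
            RuntimeWarning,
            stacklevel=2,
        )
    return {"r_mean": r_mean, "v_mean": v_mean, "posterior": p}


def posterior_mean_trajectory(
    outcomes: np.ndarray, grid: BayesianLearnerGrid = BayesianLearnerGrid()
) -> np.ndarray:
    """Per-trial predictive posterior mean of the outcome probability."""
    return run_filter(outcomes, grid)["r_mean"]
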