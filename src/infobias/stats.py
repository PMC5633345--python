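"""Group-level statistics: mixed repeated-measures ANOVA, change-score
correlations, and Fisher r-to-z comparison of correlations.

The central test of the volatility manipulation is the block volatility x
valence interaction in a mixed ANOVA on real-line-transformed learning rates
(2 within factors: block volatility, valence; 1 between factor: block order)
and on the binned pupil difference timeseries (within: block volatility,
valence, time bin).  The ANOVA is the classical balanced-design
sums-of-squares decomposition with subjects nested in the between factor:
every within effect (and its interaction with the between factor) is tested
against the corresponding effect x subject-within-group mean square.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import transform_params

__all__ = [
    "rm_anova_mixed",
    "greenhouse_geisser_epsilon",
    "change_scores",
    "correlate",
    "fisher_compare",
    "add_outcome_volatility",
    "GroupResult",
    "run_group_analysis",
]


def _ss_raw(df: pd.DataFrame, dv: str, by: tuple[str, ...], gm_n: int) -> float:
    """Raw (uncorrected) sum of squares of cell means: sum n_cell * mean^2."""
    if not by:
        return gm_n * df[dv].mean() ** 2
    g = df.groupby(list(by), observed=True)[dv]
    return float((g.count() * g.mean() ** 2).sum())


def rm_anova_mixed(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str,
    between: str | None = None,
    gg_factors: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Balanced mixed-design repeated-measures ANOVA.

    ``data`` is long-format with one observation per subject per within-cell;
    subjects are nested in the (optional) 2+-level ``between`` factor.
    Returns a table with one row per effect: sums of squares, degrees of
    freedom, F against the appropriate error stratum and the two-sided p.
    Error strata are included as rows (F and p NaN) so the full partition is
    visible.  ``gg_factors`` optionally applies a Greenhouse-Geisser
    epsilon (estimated per listed factor) to the p-values of effects
    involving that factor.

    Raises on unbalanced cells, naming the offender.
    """
    d = data.copy()
    if between is None:
        between = "_const"
        d[between] = 0
    cols = [subject, between, *within]
    for c in [dv, *cols]:
        if c not in d.columns:
            raise ValueError(f"column {c!r} missing from data")
    if d[cols + [dv]].isna().any().any():
        raise ValueError("missing values in the design columns or dv")

    # Balance checks: one observation per subject x within cell; every
    # subject maps to exactly one between level; equal group sizes.
    counts = d.groupby([subject, *within], observed=True)[dv].count()
    if counts.nunique() != 1 or counts.iloc[0] != 1:
        bad = counts[counts != counts.mode().iloc[0]]
        raise ValueError(
            f"unbalanced design: cell counts differ at {bad.index.tolist()[:5]}"
        )
    n_cells_expected = d[subject].nunique() * int(
        np.prod([d[f].nunique() for f in within])
    )
    if len(counts) != n_cells_expected:
        full = pd.MultiIndex.from_product(
            [d[subject].unique(), *[d[f].unique() for f in within]]
        )
        missing = full.difference(counts.index)
        raise ValueError(
            f"unbalanced design: missing cells {missing.tolist()[:5]}"
        )
    sub_lvls = d.groupby(subject, observed=True)[between].nunique()
    if (sub_lvls != 1).any():
        raise ValueError("each subject must belong to exactly one between level")
    group_sizes = d.groupby(between, observed=True)[subject].nunique()
    if group_sizes.nunique() != 1:
        raise ValueError(
            f"unequal between-group sizes: {group_sizes.to_dict()}"
        )
    if (group_sizes < 2).any() and group_sizes.index.size > 1:
        raise ValueError("need >= 2 subjects per between-factor level")

    n_total = len(d)
    levels = {f: d[f].nunique() for f in within}
    b = d[between].nunique()
    n_subj = d[subject].nunique()

    ss_raw = lambda by: _ss_raw(d, dv, tuple(by), n_total)
    ss0 = ss_raw(())
    ss_total = float((d[dv] ** 2).sum()) - ss0

    def ss_crossed(factors: list[str]) -> float:
        """Inclusion-exclusion SS of a crossed effect."""
        k = len(factors)
        total = 0.0
        for r in range(k + 1):
            for τ in itertools.combinations(factors, r):
                total += (-1) ** (k - r) * (ss_raw(τ) if τ else ss0)
        return total

    rows = []

    # Between stratum.
    ss_b = ss_raw((between,)) - ss0
    df_b = b - 1
    ss_sub = ss_raw((subject,)) - ss_raw((between,))
    df_sub = n_subj - b
    ms_sub = ss_sub / df_sub
    if df_b > 0:
        rows.append(
            dict(effect=between, ss=ss_b, df1=df_b, df2=df_sub,
                 F=(ss_b / df_b) / ms_sub,
                 p=sps.f.sf((ss_b / df_b) / ms_sub, df_b, df_sub))
        )
    rows.append(
        dict(effect=f"subject({between})" if df_b else "subject",
             ss=ss_sub, df1=df_sub, df2=np.nan, F=np.nan, p=np.nan)
    )

    # Greenhouse-Geisser epsilons, if requested.
    eps = {f: greenhouse_geisser_epsilon(d, dv, f, subject) for f in gg_factors}

    # Within strata.
    for r in range(1, len(within) + 1):
        for omega in itertools.combinations(within, r):
            df_w = int(np.prod([levels[f] - 1 for f in omega]))
            ss_w = ss_crossed(list(omega))
            # Error: omega x subject(between).
            ss_err = 0.0
            for rr in range(r + 1):
                for tau in itertools.combinations(omega, rr):
                    sgn = (-1) ** (r - rr)
                    ss_err += sgn * (
                        ss_raw((*tau, subject)) - ss_raw((*tau, between))
                    )
            df_err = (n_subj - b) * df_w
            ms_err = ss_err / df_err
            e = np.prod([eps[f] for f in omega if f in eps]) if eps else 1.0

            def _p(F, d1, d2):
                return sps.f.sf(F, e * d1, e * d2)

            F_w = (ss_w / df_w) / ms_err
            rows.append(
                dict(effect=" x ".join(omega), ss=ss_w, df1=df_w,
                     df2=df_err, F=F_w, p=_p(F_w, df_w, df_err))
            )
            if df_b > 0:
                ss_wb = ss_crossed([*omega, between])
                df_wb = df_b * df_w
                F_wb = (ss_wb / df_wb) / ms_err
                rows.append(
                    dict(effect=" x ".join([*omega, between]), ss=ss_wb,
                         df1=df_wb, df2=df_err, F=F_wb,
                         p=_p(F_wb, df_wb, df_err))
                )
            rows.append(
                dict(effect=" x ".join(omega) + " x subject", ss=ss_err,
                     df1=df_err, df2=np.nan, F=np.nan, p=np.nan)
            )

    table = pd.DataFrame(rows)
    table.attrs["ss_total"] = ss_total
    return table


def greenhouse_geisser_epsilon(
    data: pd.DataFrame, dv: str, factor: str, subject: str
) -> float:
    """Greenhouse-Geisser sphericity epsilon for one within factor.

    Computed from the subject x level matrix of the factor's marginal means
    (averaged over any other within factors).
    """
    wide = data.pivot_table(index=subject, columns=factor, values=dv,
                            aggfunc="mean")
    k = wide.shape[1]
    if k < 3:
        return 1.0
    S = np.cov(wide.to_numpy(), rowvar=False, ddof=1)
    mean_diag = np.trace(S) / k
    num = (k * (mean_diag - S.mean())) ** 2
    den = (k - 1) * (
        (S ** 2).sum() - 2 * k * (S.mean(axis=0) ** 2).sum() + k**2 * S.mean() ** 2
    )
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def change_scores(cohort: pd.DataFrame) -> pd.DataFrame:
    """Volatile-minus-stable change per participant and valence.

    ``cohort`` is long-format with columns ``participant, block_role``
    (``win_volatile``/``loss_volatile``), ``valence`` (``win``/``loss``),
    ``learning_rate`` and optionally ``pupil_mean6s``.  For each valence the
    learning rate is logit-transformed before differencing (volatile block
    for that valence minus stable block), so the change score can exceed
    +/-1; the pupil change is the matching raw difference of the 6 s mean
    response.  Participants missing a block are dropped with a warning.
    """
    rows = []
    for pid, g in cohort.groupby("participant"):
        for valence in ("win", "loss"):
            vol_role = f"{valence}_volatile"
            stab_role = (
                "loss_volatile" if valence == "win" else "win_volatile"
            )
            gv = g[g["valence"] == valence].set_index("block_role")
            if vol_role not in gv.index or stab_role not in gv.index:
                warnings.warn(
                    f"participant {pid} missing a block for valence "
                    f"{valence}; dropped from change scores",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            lr_key = f"alpha_{valence}"
            t_vol = transform_params(
                {lr_key: gv.loc[vol_role, "learning_rate"]}
            )[lr_key]
            t_stab = transform_params(
                {lr_key: gv.loc[stab_role, "learning_rate"]}
            )[lr_key]
            row = {
                "participant": pid,
                "valence": valence,
                "d_learning_rate": t_vol - t_stab,
            }
            if "pupil_mean6s" in gv.columns:
                row["d_pupil"] = (
                    gv.loc[vol_role, "pupil_mean6s"]
                    - gv.loc[stab_role, "pupil_mean6s"]
                )
            rows.append(row)
    return pd.DataFrame(rows)


def correlate(x, y) -> dict[str, float]:
    """Pearson correlation with df = n - 2 and two-sided t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two aligned samples of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "df": x.size - 2, "p": float(p), "n": int(x.size)}


def fisher_compare(r1: float, r2: float, n1: int, n2: int) -> dict[str, float]:
    """Compare two independent correlations via the Fisher z transform.

    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p-value.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both samples must have n > 3")
    for r in (r1, r2):
        if not -1 < r < 1:
            raise ValueError(f"correlation {r} must lie in (-1, 1)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return {"z": float(z), "p": float(2 * sps.norm.sf(abs(z)))}


def add_outcome_volatility(long: pd.DataFrame) -> pd.DataFrame:
    """Recode block volatility as outcome volatility.

    Outcome volatility is ``volatile`` when the row's valence matches the
    block's volatile outcome (win rows in the win-volatile block, loss rows
    in the loss-volatile block) and ``stable`` otherwise.  Used for the
    asymmetry test of whether the volatility effect differs between
    valences.
    """
    out = long.copy()
    match = (
        (out["valence"] == "win") & (out["block_role"] == "win_volatile")
    ) | ((out["valence"] == "loss") & (out["block_role"] == "loss_volatile"))
    out["outcome_volatility"] = np.where(match, "volatile", "stable")
    return out


@dataclass
class GroupResult:
    """Container for the cohort-level analysis battery."""

    behaviour_anova: pd.DataFrame | None = None
    pupil_anova: pd.DataFrame | None = None
    outcome_volatility_anova: pd.DataFrame | None = None
    correlations: dict = field(default_factory=dict)
    fisher: dict | None = None
    n_behaviour: int = 0
    n_pupil: int = 0


def run_group_analysis(
    behaviour: pd.DataFrame, pupil_bins: pd.DataFrame | None = None
) -> GroupResult:
    """The cohort analysis battery on blocks 2-3 data.

    ``behaviour``: long-format, one row per participant x block_role x
    valence with columns ``participant, block_order, block_role, valence,
    learning_rate`` (raw scale; transformed internally) and optionally
    ``pupil_mean6s``.  ``pupil_bins``: per participant x block_role x
    valence x bin column ``difference`` plus ``block_order``.

    Runs: the 2x2(xorder) ANOVA on transformed learning rates; the
    2x2x6(xorder) ANOVA on binned pupil differences; the outcome-volatility
    recoded ANOVA on the pupil data; win and loss change-score correlations
    with the Fisher z comparison (when pupil means are present).
    """
    res = GroupResult()
    beh = behaviour.copy()
    beh["t_learning_rate"] = [
        transform_params({"alpha_win": v})["alpha_win"]
        for v in beh["learning_rate"]
    ]
    res.n_behaviour = beh["participant"].nunique()
    res.behaviour_anova = rm_anova_mixed(
        beh,
        dv="t_learning_rate",
        within=["block_role", "valence"],
        subject="participant",
        between="block_order",
    )
    if pupil_bins is not None:
        pb = pupil_bins.dropna(subset=["difference"])
        complete = (
            pb.groupby("participant")["difference"].count()
        )
        full = complete[complete == complete.max()].index
        pb = pb[pb["participant"].isin(full)]
        res.n_pupil = pb["participant"].nunique()
        res.pupil_anova = rm_anova_mixed(
            pb,
            dv="difference",
            within=["block_role", "valence", "bin"],
            subject="participant",
            between="block_order",
        )
        res.outcome_volatility_anova = rm_anova_mixed(
            add_outcome_volatility(pb),
            dv="difference",
            within=["outcome_volatility", "valence", "bin"],
            subject="participant",
            between="block_order",
        )
    if "pupil_mean6s" in behaviour.columns:
        cs = change_scores(behaviour.dropna(subset=["pupil_mean6s"]))
        for valence in ("win", "loss"):
            sub = cs[cs["valence"] == valence]
            if len(sub) >= 3:
                res.correlations[valence] = correlate(
                    sub["d_pupil"], sub["d_learning_rate"]
                )
        if {"win", "loss"} <= set(res.correlations):
            cw, cl = res.correlations["win"], res.correlations["loss"]
            res.fisher = fisher_compare(
                cl["r"], cw["r"], cl["n"], cw["n"]
            )
    return res
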