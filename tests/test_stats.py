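import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from infobias import stats
from infobias.stats import (
    add_outcome_volatility,
    change_scores,
    correlate,
    fisher_compare,
    greenhouse_geisser_epsilon,
    rm_anova_mixed,
    run_group_analysis,
)


def _cohort_2x2(rng, n_per_group=8, interaction=0.0, noise=0.5):
    """Long-format 2 (block_role) x 2 (valence) within x 2 between design."""
    rows = []
    for order in ("winfirst", "lossfirst"):
        for s in range(n_per_group):
            sid = f"{order}_{s}"
            base = rng.normal(0, 0.8)
            for br in ("win_volatile", "loss_volatile"):
                for val in ("win", "loss"):
                    sign = 1.0 if (br == "win_volatile") == (val == "win") else -1.0
                    rows.append(
                        dict(
                            participant=sid,
                            block_order=order,
                            block_role=br,
                            valence=val,
                            y=base + sign * interaction + rng.normal(0, noise),
                        )
                    )
    return pd.DataFrame(rows)


def _oracle_2x2_mixed(df):
    """Brute-force contrast oracle for the 2x2 within x between design.

    Two-level within effects reduce to t-tests on per-subject contrast
    scores: one-sample (pooled within groups) for the main effect, and
    two-sample between groups for the effect x group interaction.
    """
    wide = df.pivot_table(
        index=["participant", "block_order"],
        columns=["block_role", "valence"],
        values="y",
    )
    g = wide.index.get_level_values("block_order")
    out = {}
    contrasts = {
        "block_role": wide[("win_volatile",)].mean(axis=1)
        - wide[("loss_volatile",)].mean(axis=1),
        "valence": wide.xs("win", axis=1, level="valence").mean(axis=1)
        - wide.xs("loss", axis=1, level="valence").mean(axis=1),
        "block_role x valence": (
            wide[("win_volatile", "win")]
            - wide[("win_volatile", "loss")]
            - wide[("loss_volatile", "win")]
            + wide[("loss_volatile", "loss")]
        ),
    }
    groups = sorted(set(g))
    for name, c in contrasts.items():
        parts = [c[g == lvl] for lvl in groups]
        n = c.size
        pooled = sum(((p - p.mean()) ** 2).sum() for p in parts) / (
            n - len(groups)
        )
        grand = np.mean([p.mean() for p in parts])
        out[name] = n * grand**2 / pooled
        t2 = sps.ttest_ind(parts[0], parts[1]).statistic ** 2
        out[f"{name} x block_order"] = float(t2)
    return out


class TestMixedAnova:
    def test_flat_data_has_zero_interaction(self):
        df = _cohort_2x2(np.random.default_rng(0), interaction=0.0, noise=0.0)
        df["y"] = 1.0
        tab = rm_anova_mixed(
            df, "y", within=["block_role", "valence"],
            subject="participant", between="block_order",
        ).set_index("effect")
        assert tab.loc["block_role x valence", "ss"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_crossover_loads_only_the_interaction(self):
        df = _cohort_2x2(np.random.default_rng(1), interaction=1.0, noise=0.0)
        # remove the random subject offsets to make the design exactly pure
        df["y"] -= df.groupby("participant")["y"].transform("mean")
        tab = rm_anova_mixed(
            df, "y", within=["block_role", "valence"],
            subject="participant", between="block_order",
        ).set_index("effect")
        assert tab.loc["block_role x valence", "ss"] == pytest.approx(
            tab.attrs["ss_total"], rel=1e-10
        )
        assert tab.loc["block_role", "ss"] == pytest.approx(0.0, abs=1e-10)
        assert tab.loc["valence", "ss"] == pytest.approx(0.0, abs=1e-10)

    def test_sum_of_squares_partitions_total(self):
        df = _cohort_2x2(np.random.default_rng(2), interaction=0.4)
        tab = rm_anova_mixed(
            df, "y", within=["block_role", "valence"],
            subject="participant", between="block_order",
        )
        assert tab["ss"].sum() == pytest.approx(tab.attrs["ss_total"], abs=1e-8)

    @pytest.mark.parametrize("n_per_group", [3, 6])
    def test_agrees_with_contrast_oracle(self, n_per_group):
        df = _cohort_2x2(
            np.random.default_rng(3), n_per_group=n_per_group, interaction=0.3
        )
        tab = rm_anova_mixed(
            df, "y", within=["block_role", "valence"],
            subject="participant", between="block_order",
        ).set_index("effect")
        oracle = _oracle_2x2_mixed(df)
        for effect, F in oracle.items():
            assert tab.loc[effect, "F"] == pytest.approx(F, abs=1e-8), effect

    def test_agrees_with_pingouin_on_one_within_design(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        rows = []
        for grp in ("a", "b"):
            for s in range(9):
                base = rng.normal()
                for w in ("x", "y"):
                    rows.append(
                        dict(subj=f"{grp}{s}", grp=grp, w=w,
                             score=base + (0.6 if w == "x" else 0)
                             + rng.normal(0, 0.5))
                    )
        df = pd.DataFrame(rows)
        ours = rm_anova_mixed(
            df, "score", within=["w"], subject="subj", between="grp"
        ).set_index("effect")
        theirs = pg.mixed_anova(
            df, dv="score", within="w", subject="subj", between="grp"
        ).set_index("Source")
        assert ours.loc["grp", "F"] == pytest.approx(theirs.loc["grp", "F"])
        assert ours.loc["w", "F"] == pytest.approx(theirs.loc["w", "F"])
        assert ours.loc["w x grp", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"]
        )

    def test_unbalanced_cells_rejected(self):
        df = _cohort_2x2(np.random.default_rng(5))
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova_mixed(
                df.iloc[:-1], "y", within=["block_role", "valence"],
                subject="participant", between="block_order",
            )

    def test_pure_within_design_without_between(self):
        df = _cohort_2x2(np.random.default_rng(6), interaction=0.5)
        tab = rm_anova_mixed(
            df, "y", within=["block_role", "valence"], subject="participant"
        ).set_index("effect")
        assert "block_order" not in tab.index
        assert np.isfinite(tab.loc["block_role x valence", "F"])

    def test_gg_epsilon_bounds(self):
        rng = np.random.default_rng(7)
        rows = []
        for s in range(12):
            for b in range(6):
                rows.append(dict(subj=s, bin=b, score=rng.normal() + 0.3 * b))
        df = pd.DataFrame(rows)
        eps = greenhouse_geisser_epsilon(df, "score", "bin", "subj")
        assert 1.0 / 5.0 <= eps <= 1.0
        # two-level factors need no correction
        df2 = _cohort_2x2(np.random.default_rng(8))
        assert greenhouse_geisser_epsilon(
            df2, "y", "valence", "participant"
        ) == 1.0


class TestChangeScores:
    @staticmethod
    def _table(lr_wv, lr_lv, valence="loss", pupil=None):
        rows = []
        for role, lr in (("win_volatile", lr_wv), ("loss_volatile", lr_lv)):
            row = dict(participant=1, block_role=role, valence=valence,
                       learning_rate=lr)
            if pupil is not None:
                row["pupil_mean6s"] = pupil[role]
            rows.append(row)
        return pd.DataFrame(rows)

    def test_identical_blocks_give_zero(self):
        cs = change_scores(self._table(0.4, 0.4))
        assert cs["d_learning_rate"].iloc[0] == pytest.approx(0.0)

    def test_logit_difference_value(self):
        # loss valence: volatile block is the loss-volatile one
        cs = change_scores(self._table(lr_wv=0.5, lr_lv=0.8))
        assert cs["d_learning_rate"].iloc[0] == pytest.approx(np.log(4.0))

    def test_change_can_exceed_one(self):
        cs = change_scores(self._table(lr_wv=0.1, lr_lv=0.9))
        assert cs["d_learning_rate"].iloc[0] > 1.0

    def test_pupil_delta_is_volatile_minus_stable(self):
        cs = change_scores(
            self._table(0.5, 0.5, pupil={"win_volatile": 0.1,
                                         "loss_volatile": 0.4})
        )
        assert cs["d_pupil"].iloc[0] == pytest.approx(0.3)

    def test_missing_block_drops_participant(self):
        df = self._table(0.4, 0.6).iloc[:1]
        with pytest.warns(RuntimeWarning, match="missing a block"):
            cs = change_scores(df)
        assert cs.empty


class TestCorrelate:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1)
        assert res["r"] == pytest.approx(1.0)
        assert res["df"] == 8

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        r_hand = np.sum((x - 3) * (y - y.mean())) / np.sqrt(
            np.sum((x - 3) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        res = correlate(x, y)
        assert res["r"] == pytest.approx(r_hand, abs=1e-12)
        assert res["df"] == 3

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(9)
        res = correlate(rng.normal(size=2000), rng.normal(size=2000))
        assert abs(res["r"]) < 0.1

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            correlate(np.ones(5), np.arange(5.0))


class TestFisherCompare:
    def test_equal_correlations_give_zero(self):
        assert fisher_compare(0.4, 0.4, 20, 20)["z"] == pytest.approx(0.0)

    def test_published_values(self):
        res = fisher_compare(0.50, -0.08, 29, 29)
        assert res["z"] == pytest.approx(2.27, abs=0.005)
        assert res["p"] == pytest.approx(0.023, abs=0.002)

    def test_direct_formula_value(self):
        res = fisher_compare(0.9, 0.0, 50, 50)
        assert res["z"] == pytest.approx(
            np.arctanh(0.9) / np.sqrt(2.0 / 47.0), abs=1e-10
        )

    def test_antisymmetric(self):
        a = fisher_compare(0.6, 0.2, 30, 25)
        b = fisher_compare(0.2, 0.6, 25, 30)
        assert a["z"] == pytest.approx(-b["z"])

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            fisher_compare(0.5, 0.1, 3, 20)


class TestOutcomeVolatilityRecoding:
    def test_matches_definition(self):
        df = pd.DataFrame(
            {
                "block_role": ["win_volatile", "win_volatile",
                               "loss_volatile", "loss_volatile"],
                "valence": ["win", "loss", "win", "loss"],
            }
        )
        out = add_outcome_volatility(df)
        assert out["outcome_volatility"].tolist() == [
            "volatile", "stable", "stable", "volatile"
        ]


class TestGroupAnalysis:
    def test_injected_interaction_detected(self):
        rng = np.random.default_rng(10)
        rows = []
        for i, order in enumerate(8 * ["winfirst"] + 8 * ["lossfirst"]):
            for br in ("win_volatile", "loss_volatile"):
                for val in ("win", "loss"):
                    volatile = (br == f"{val}_volatile")
                    lr = 0.45 if volatile else 0.15
                    lr = float(np.clip(lr + rng.normal(0, 0.04), 0.02, 0.98))
                    rows.append(
                        dict(participant=i, block_order=order, block_role=br,
                             valence=val, learning_rate=lr,
                             pupil_mean6s=(0.4 if volatile else 0.1)
                             + rng.normal(0, 0.1))
                    )
        beh = pd.DataFrame(rows)
        res = run_group_analysis(beh)
        tab = res.behaviour_anova.set_index("effect")
        assert tab.loc["block_role x valence", "p"] < 0.001
        assert res.n_behaviour == 16
        assert "win" in res.correlations and "loss" in res.correlations
        assert res.fisher is not None
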