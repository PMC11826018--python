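"""Model-free analysis: proportions, FAE curve, mixed ANOVA vs. oracles."""

import numpy as np
import pandas as pd
import pytest

from faeddm.generate import generate_experiment, preset_paper_like
from faeddm.model_free import (
    _gg_epsilon,
    _mauchly,
    fae_curve,
    mixed_anova,
    response_proportions,
)

from tests_helpers import ADAPTORS, MORPHS, proportion_table as prop_table
from tests_helpers import random_proportion_table as random_table


class TestProportions:
    def test_hand_count(self):
        rows = (
            [("p", "NT", "androgynous", 20, i, "male", 400.0) for i in range(5)]
            + [("p", "NT", "androgynous", 20, 5 + i, "female", 400.0) for i in range(2)]
            + [("p", "NT", "androgynous", 20, 7, "omitted", np.nan)]
        )
        trials = pd.DataFrame(
            rows, columns=["participant_id", "group", "adaptor", "morph_pct", "trial_index", "response", "rt_ms"]
        )
        tab = response_proportions(trials)
        assert tab.loc[0, "prop_male"] == pytest.approx(5 / 7)
        assert tab.loc[0, "n_responded"] == 7

    def test_always_male_participant(self, tiny_cohort):
        _, trials, _ = tiny_cohort
        mono = trials.copy()
        responded = mono["response"] != "omitted"
        mono.loc[responded, "response"] = "male"
        tab = response_proportions(mono)
        assert (tab.loc[~tab["missing"], "prop_male"] == 1.0).all()

    def test_ordering_by_construction(self, tiny_cohort):
        _, trials, _ = tiny_cohort
        tab = response_proportions(trials)
        m80 = tab[tab["morph_pct"] == 80]["prop_male"].mean()
        m20 = tab[tab["morph_pct"] == 20]["prop_male"].mean()
        assert m80 > m20

    def test_fully_omitted_cell_flagged_missing(self):
        rows = [("p", "NT", "androgynous", 20, i, "omitted", np.nan) for i in range(4)]
        rows += [("p", "NT", "androgynous", 40, i, "male", 400.0) for i in range(4)]
        trials = pd.DataFrame(
            rows, columns=["participant_id", "group", "adaptor", "morph_pct", "trial_index", "response", "rt_ms"]
        )
        tab = response_proportions(trials)
        row = tab[tab["morph_pct"] == 20].iloc[0]
        assert row["missing"] and np.isnan(row["prop_male"])


class TestFaeCurve:
    def test_identical_conditions_give_zero(self):
        vals, groups = {}, {}
        for pid in ("a1", "a2"):
            groups[pid] = "AUT"
            for ad in ADAPTORS:
                for m in MORPHS:
                    vals[(pid, ad, m)] = 0.1 + m / 100
        curve = fae_curve(prop_table(vals, groups))
        assert np.allclose(curve["fae"], 0.0)

    def test_label_swap_flips_sign(self, rng):
        tab = random_table(rng, 3, 3)
        swapped = tab.copy()
        swapped["adaptor"] = swapped["adaptor"].map(
            {"androgynous": "male", "male": "androgynous"}
        )
        c1 = fae_curve(tab).sort_values(["participant_id", "morph_pct"])
        c2 = fae_curve(swapped).sort_values(["participant_id", "morph_pct"])
        assert np.allclose(c1["fae"].to_numpy(), -c2["fae"].to_numpy())

    def test_adaptor_shift_scenario_positive_interior_peak(self):
        """Constant drift shifts produce the inverted-U FAE curve."""
        cfg = preset_paper_like(
            "adaptor_shift_only",
            n_per_group={"AUT": 6, "NT": 6},
            trials_per_morph=32,
            omission_rate=0.0,
            fast_guess_rate=0.0,
            slow_outlier_rate=0.0,
            resolution=4e-4,
            seed=77,
        )
        trials, _ = generate_experiment(cfg)
        curve = fae_curve(response_proportions(trials))
        by_morph = curve.groupby("morph_pct")["fae"].mean()
        assert (by_morph > 0).all()
        assert max(by_morph[40], by_morph[60]) > max(by_morph[20], by_morph[80])


def brute_force_anova(Y_aut, Y_nt):
    """Textbook balanced mixed-design sums of squares from cell means.

    Independent oracle: plain loops over the A(between) x B(2, within) x
    C(4, within) means decomposition; requires equal group sizes.
    """
    Y = np.stack([Y_aut, Y_nt])  # (g, n, J, K)
    g, n, J, K = Y.shape
    GM = Y.mean()
    Mg = Y.mean(axis=(1, 2, 3))
    Mgi = Y.mean(axis=(2, 3))
    Mj = Y.mean(axis=(0, 1, 3))
    Mk = Y.mean(axis=(0, 1, 2))
    Mgj = Y.mean(axis=(1, 3))
    Mgk = Y.mean(axis=(1, 2))
    Mjk = Y.mean(axis=(0, 1))
    Mgjk = Y.mean(axis=1)
    Mgij = Y.mean(axis=3)
    Mgik = Y.mean(axis=2)

    ss = {}
    ss["Group"] = n * J * K * np.sum((Mg - GM) ** 2)
    ss["subj"] = J * K * np.sum((Mgi - Mg[:, None]) ** 2)
    ss["Adaptor"] = g * n * K * np.sum((Mj - GM) ** 2)
    ss["Adaptor x Group"] = n * K * np.sum((Mgj - Mg[:, None] - Mj[None, :] + GM) ** 2)
    ss["err_B"] = K * np.sum((Mgij - Mgi[:, :, None] - Mgj[:, None, :] + Mg[:, None, None]) ** 2)
    ss["Morph"] = g * n * J * np.sum((Mk - GM) ** 2)
    ss["Morph x Group"] = n * J * np.sum((Mgk - Mg[:, None] - Mk[None, :] + GM) ** 2)
    ss["err_C"] = J * np.sum((Mgik - Mgi[:, :, None] - Mgk[:, None, :] + Mg[:, None, None]) ** 2)
    ss["Adaptor x Morph"] = g * n * np.sum(
        (Mjk - Mj[:, None] - Mk[None, :] + GM) ** 2
    )
    ss["Adaptor x Morph x Group"] = n * np.sum(
        (
            Mgjk
            - Mgj[:, :, None]
            - Mgk[:, None, :]
            - Mjk[None, :, :]
            + Mg[:, None, None]
            + Mj[None, :, None]
            + Mk[None, None, :]
            - GM
        )
        ** 2
    )
    resid = (
        Y
        - Mgjk[:, None, :, :]
        - Mgij[:, :, :, None]
        - Mgik[:, :, None, :]
        + Mgi[:, :, None, None]
        + Mgj[:, None, :, None]
        + Mgk[:, None, None, :]
        - Mg[:, None, None, None]
    )
    ss["err_BC"] = np.sum(resid**2)

    dfs = {
        "Group": (g - 1, g * (n - 1)),
        "Adaptor": (J - 1, g * (n - 1) * (J - 1)),
        "Adaptor x Group": ((g - 1) * (J - 1), g * (n - 1) * (J - 1)),
        "Morph": (K - 1, g * (n - 1) * (K - 1)),
        "Morph x Group": ((g - 1) * (K - 1), g * (n - 1) * (K - 1)),
        "Adaptor x Morph": ((J - 1) * (K - 1), g * (n - 1) * (J - 1) * (K - 1)),
        "Adaptor x Morph x Group": (
            (g - 1) * (J - 1) * (K - 1),
            g * (n - 1) * (J - 1) * (K - 1),
        ),
    }
    err_of = {
        "Group": "subj",
        "Adaptor": "err_B",
        "Adaptor x Group": "err_B",
        "Morph": "err_C",
        "Morph x Group": "err_C",
        "Adaptor x Morph": "err_BC",
        "Adaptor x Morph x Group": "err_BC",
    }
    out = {}
    for eff, (df1, df2) in dfs.items():
        F = (ss[eff] / df1) / (ss[err_of[eff]] / df2)
        out[eff] = (ss[eff], df1, df2, F)
    return out


class TestMixedAnova:
    def _wide(self, table):
        return table.pivot_table(
            index=["participant_id", "group"],
            columns=["adaptor", "morph_pct"],
            values="prop_male",
        )

    def test_matches_brute_force_oracle_on_balanced_toy(self, rng):
        tab = random_table(rng, 4, 4)
        wide = self._wide(tab)
        Y_aut = wide.loc[[i for i in wide.index if i[1] == "AUT"]].to_numpy().reshape(4, 2, 4)
        Y_nt = wide.loc[[i for i in wide.index if i[1] == "NT"]].to_numpy().reshape(4, 2, 4)
        oracle = brute_force_anova(Y_aut, Y_nt)
        res = mixed_anova(tab)
        for eff, (ss, df1, df2, F) in oracle.items():
            row = res.effects.loc[eff]
            assert row["ss"] == pytest.approx(ss, abs=1e-10)
            assert (row["df1"], row["df2"]) == (df1, df2)
            assert row["F"] == pytest.approx(F, rel=1e-10)

    def test_frozen_r_oracle(self):
        """Agreement with car::Anova / stats::mauchly.test / car::leveneTest.

        The fixture is regenerated deterministically; the expected numbers
        were computed once with R 4.3 (type III, contr.sum) and frozen.
        """
        rng = np.random.RandomState(2024)
        rows = []
        for g, n in (("AUT", 6), ("NT", 8)):
            for i in range(n):
                base = rng.uniform(0.2, 0.4)
                for a_i, ad in enumerate(ADAPTORS):
                    for m_i, m in enumerate(MORPHS):
                        p = base + 0.15 * m_i - 0.1 * a_i + 0.05 * rng.standard_normal()
                        rows.append((f"{g}{i:02d}", g, ad, m, float(np.clip(p, 0, 1))))
        tab = pd.DataFrame(
            rows, columns=["participant_id", "group", "adaptor", "morph_pct", "prop_male"]
        )
        res = mixed_anova(tab)
        expected = {
            # effect: (SS, F, p)
            "Group": (0.0003455464, 0.0244866636, 8.782548e-01),
            "Adaptor": (0.2008289430, 81.6519699769, 1.058308e-06),
            "Adaptor x Group": (0.0002421572, 0.0984550134, 7.590791e-01),
            "Morph": (3.5691330548, 380.7158083512, 2.596854e-27),
            "Morph x Group": (0.0011136927, 0.1187964775, 9.484753e-01),
            "Adaptor x Morph": (0.0135752007, 1.4740359613, 2.379137e-01),
            "Adaptor x Morph x Group": (0.0032765627, 0.3557789950, 7.852327e-01),
        }
        for eff, (ss, F, p) in expected.items():
            row = res.effects.loc[eff]
            assert row["ss"] == pytest.approx(ss, rel=1e-6)
            assert row["F"] == pytest.approx(F, rel=1e-6)
            assert row["p"] == pytest.approx(p, rel=1e-4)
        assert res.effects.loc["Morph", "eps"] == pytest.approx(0.8563080823, rel=1e-8)
        assert res.effects.loc["Adaptor x Morph", "eps"] == pytest.approx(0.8110687108, rel=1e-8)
        assert res.effects.loc["Morph x Group", "p_corr"] == pytest.approx(9.286159e-01, rel=1e-5)
        assert res.effects.loc["Adaptor x Morph", "p_corr"] == pytest.approx(2.447333e-01, rel=1e-5)
        assert res.mauchly.loc["Morph", "W"] == pytest.approx(0.7394977190, abs=1e-9)
        assert res.mauchly.loc["Adaptor x Morph", "W"] == pytest.approx(0.6896397926, abs=1e-9)
        # R's second-order Box term uses the original cell count; ours the
        # contrast dimension, hence the loose tolerance on p
        assert res.mauchly.loc["Morph", "p"] == pytest.approx(0.6649911176, abs=5e-4)
        assert res.mauchly.loc["Adaptor x Morph", "p"] == pytest.approx(0.5533114849, abs=5e-4)
        assert res.levene[0] == pytest.approx(2.58421, abs=1e-4)
        assert res.levene[1] == pytest.approx(0.13391, abs=1e-4)

    def test_group_denominator_df_for_68_participants(self, rng):
        tab = random_table(rng, 29, 39)
        res = mixed_anova(tab)
        assert res.effects.loc["Group", "df2"] == 66
        assert res.n_per_group == {"AUT": 29, "NT": 39}

    def test_two_level_factor_sphericity_is_vacuous(self, rng):
        res = mixed_anova(random_table(rng, 4, 4))
        assert "Adaptor" not in res.mauchly.index  # no test needed at 2 levels
        assert res.effects.loc["Adaptor", "df1_corr"] == 1.0  # epsilon = 1
        W, _, p = _mauchly(np.eye(1), 10)
        assert (W, p) == (1.0, 1.0)
        assert _gg_epsilon(np.eye(1)) == 1.0

    def test_epsilon_bounds(self, rng):
        for _ in range(5):
            S = np.cov(rng.standard_normal((3, 40)))
            eps = _gg_epsilon(S)
            assert 1 / 2 - 1e-12 <= eps <= 1 + 1e-12  # q=2... k-1 lower bound
        S4 = np.cov(rng.standard_normal((3, 60)))
        assert 1 / 3 - 1e-12 <= _gg_epsilon(S4) <= 1 + 1e-12

    def test_group_label_swap_preserves_within_F(self, rng):
        tab = random_table(rng, 4, 6)
        swapped = tab.copy()
        swapped["group"] = swapped["group"].map({"AUT": "NT", "NT": "AUT"})
        r1 = mixed_anova(tab)
        r2 = mixed_anova(swapped)
        for eff in ("Adaptor", "Morph", "Adaptor x Morph"):
            assert r1.effects.loc[eff, "F"] == pytest.approx(r2.effects.loc[eff, "F"], rel=1e-12)

    def test_ss_additivity_balanced(self, rng):
        tab = random_table(rng, 5, 5)
        wide = self._wide(tab)
        Y = wide.to_numpy()
        total = np.sum((Y - Y.mean()) ** 2)
        res = mixed_anova(tab)
        eff_ss = res.effects["ss"].sum()
        err_ss = (
            res.effects.loc["Group", "ss_error"]
            + res.effects.loc["Adaptor", "ss_error"]
            + res.effects.loc["Morph", "ss_error"]
            + res.effects.loc["Adaptor x Morph", "ss_error"]
        )
        assert eff_ss + err_ss == pytest.approx(total, abs=1e-8)

    def test_missing_cells_drop_participant(self, rng):
        tab = random_table(rng, 4, 4)
        tab = tab[~((tab["participant_id"] == "AUT00") & (tab["morph_pct"] == 40))]
        res = mixed_anova(tab)
        assert res.dropped_participants == ["AUT00"]
        assert res.n_per_group["AUT"] == 3

    def test_too_few_participants_error(self, rng):
        tab = random_table(rng, 1, 4)
        with pytest.raises(ValueError):
            mixed_anova(tab)

    def test_null_scenario_type_one_error_rate(self):
        """Uncorrected Group-effect false-positive rate sits near 5%."""
        from scipy.stats import binom

        hits = 0
        n_rep = 200
        for r in range(n_rep):
            cfg = preset_paper_like(
                "null",
                n_per_group={"AUT": 6, "NT": 6},
                trials_per_morph=8,
                resolution=5e-4,
                seed=30_000 + r,
            )
            trials, _ = generate_experiment(cfg)
            res = mixed_anova(response_proportions(trials))
            hits += res.effects.loc["Group", "p"] < 0.05
        lo, hi = binom.interval(0.95, n_rep, 0.05)
        assert lo <= hits <= hi
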