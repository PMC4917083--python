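import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import taplearn as tl
from taplearn import inferstats
from taplearn.errors import DegenerateInputError, DesignError


def anova_projection_oracle(y, factors, factor_names, interaction_order=2):
    """Brute-force factorial ANOVA for balanced designs.

    Computes each effect's SS by projecting the response onto the
    explicit effect-contrast vector (orthogonal under balance) and the
    residual SS from the saturated cell-means fit restricted to the
    included effects.  Independent of the least-squares refitting used
    by the implementation.
    """
    import itertools
    y = np.asarray(y, dtype=float)
    codes = {}
    for name in factor_names:
        levels = sorted(factors[name].unique())
        codes[name] = np.where(factors[name].to_numpy() == levels[1], 1.0, -1.0)
    out = {}
    columns = [np.ones_like(y)]
    for order in range(1, interaction_order + 1):
        for combo in itertools.combinations(factor_names, order):
            c = np.ones_like(y)
            for name in combo:
                c = c * codes[name]
            out[":".join(combo)] = (c @ y) ** 2 / (c @ c)
            columns.append(c)
    X = np.column_stack(columns)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ss_res = float(np.sum((y - X @ beta) ** 2))
    df_den = len(y) - X.shape[1]
    ms = ss_res / df_den
    return {k: (ss, ss / ms) for k, ss in out.items()}, ss_res, df_den


class TestConsolidationScore:
    def test_last3(self):
        sc = tl.consolidation_score(
            [1, 2, 5, 10, 11, 12], [13, 14, 15], "last3"
        )
        assert sc.raw == pytest.approx(3.0)
        assert sc.transformed == pytest.approx(np.sqrt(3))

    def test_zero_difference(self):
        sc = tl.consolidation_score([9, 10, 11], [9, 10, 11], "last3")
        assert sc.raw == 0.0 and sc.transformed == 0.0

    def test_best3_uses_top_values(self):
        day1 = [2, 9, 4, 8, 3, 10, 5, 5, 5]
        best = tl.consolidation_score(day1, [10, 10, 10], "best3")
        last = tl.consolidation_score(day1, [10, 10, 10], "last3")
        assert best.raw == pytest.approx(10 - 9.0)
        assert last.raw == pytest.approx(10 - 5.0)

    def test_signed_root_of_negative(self):
        sc = tl.consolidation_score([10, 10, 10], [6, 6, 6], "last3")
        assert sc.raw == -4.0 and sc.transformed == -2.0

    def test_trial_count_errors(self):
        with pytest.raises(ValueError):
            tl.consolidation_score([1, 2], [3, 4, 5])
        with pytest.raises(ValueError):
            tl.consolidation_score([1, 2, 3], [4, 5])

    @given(
        day1=st.lists(st.floats(0, 50), min_size=3, max_size=12),
        day2=st.lists(st.floats(0, 50), min_size=3, max_size=3),
    )
    def test_score_is_mean_of_differences(self, day1, day2):
        # difference of means equals mean of paired differences with the
        # final three day-1 trials
        sc = tl.consolidation_score(day1, day2, "last3")
        paired = np.mean(np.asarray(day2) - np.asarray(day1[-3:]))
        assert sc.raw == pytest.approx(paired, abs=1e-9)
        assert sc.transformed**2 == pytest.approx(abs(sc.raw), abs=1e-9)
        assert np.sign(sc.transformed) == np.sign(sc.raw)

    def test_transform_reduces_skewness(self):
        rng = np.random.default_rng(4)
        raw = rng.gamma(2.0, 1.5, size=200) - 0.5
        transformed = tl.signed_sqrt(raw)
        assert abs(stats.skew(transformed)) < abs(stats.skew(raw))


class TestFactorialAnova:
    def test_hand_computed_2x2(self, toy_2x2):
        y, factors = toy_2x2
        tab = tl.factorial_anova(y, factors).set_index("effect")
        assert tab.loc["A", "ss"] == pytest.approx(32.0)
        assert tab.loc["B", "ss"] == pytest.approx(2.0)
        assert tab.loc["A:B", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc["Residual", "ss"] == pytest.approx(8.0)
        assert tab.loc["Residual", "df_num"] == 4
        assert tab.loc["A", "F"] == pytest.approx(16.0)
        assert tab.loc["B", "F"] == pytest.approx(1.0)

    def test_main_design_df_den_117(self, main_cohort):
        factors, trials, _ = main_cohort
        scores = tl.consolidation_scores(trials)
        tab = tl.factorial_anova(scores["transformed"].to_numpy(), factors)
        effects = tab[tab["effect"] != "Residual"]
        assert len(effects) == 10  # 4 mains + 6 two-way interactions
        assert (effects["df_den"] == 117).all()
        assert effects["p"].between(0, 1).all()

    def test_constant_response(self, toy_2x2):
        _, factors = toy_2x2
        tab = tl.factorial_anova(np.full(8, 2.5), factors)
        effects = tab[tab["effect"] != "Residual"]
        assert np.allclose(effects["ss"], 0.0)

    def test_balanced_ss_decomposition(self, main_cohort):
        factors, _, _ = main_cohort
        rng = np.random.default_rng(3)
        y = rng.normal(size=len(factors))
        tab = tl.factorial_anova(y, factors)
        total = np.sum((y - y.mean()) ** 2)
        assert tab["ss"].sum() == pytest.approx(total, rel=1e-9)

    def test_matches_projection_oracle_balanced(self):
        rng = np.random.default_rng(9)
        factors = tl.generate_design(2, seed=4)  # 32 subjects
        y = rng.normal(size=len(factors))
        names = ["piano", "age_group", "intelligence", "gender"]
        oracle, ss_res, df_den = anova_projection_oracle(y, factors, names)
        tab = tl.factorial_anova(y, factors).set_index("effect")
        for effect, (ss, F) in oracle.items():
            assert tab.loc[effect, "ss"] == pytest.approx(ss, rel=1e-9)
            assert tab.loc[effect, "F"] == pytest.approx(F, rel=1e-9)
        assert tab.loc["Residual", "ss"] == pytest.approx(ss_res, rel=1e-9)

    def test_matches_statsmodels_type3_unbalanced(self):
        # independent route: statsmodels OLS with sum coding, Type-III SS
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        factors, trials, _ = tl.scenario_cohort("control1", seed=6)
        y = tl.consolidation_scores(trials)["transformed"].to_numpy()
        df = factors.assign(y=y)
        formula = (
            "y ~ (C(piano, Sum) + C(age_group, Sum) + C(intelligence, Sum)"
            " + C(gender, Sum)) ** 2"
        )
        sm_tab = sm.stats.anova_lm(smf.ols(formula, data=df).fit(), typ=3)
        tab = tl.factorial_anova(y, factors).set_index("effect")
        rename = {
            "C(piano, Sum)": "piano",
            "C(age_group, Sum)": "age_group",
            "C(intelligence, Sum)": "intelligence",
            "C(gender, Sum)": "gender",
        }
        for sm_name, F in sm_tab["F"].items():
            if sm_name in ("Intercept", "Residual"):
                continue
            parts = [rename[p] for p in sm_name.split(":")]
            ours = next(
                lab for lab in tab.index
                if lab != "Residual" and set(lab.split(":")) == set(parts)
            )
            assert tab.loc[ours, "F"] == pytest.approx(F, rel=1e-8)

    def test_rank_deficient_design(self):
        factors = pd.DataFrame(
            {"A": ["a0", "a0", "a1", "a1"], "B": ["b0", "b0", "b1", "b1"]}
        )
        with pytest.raises(DesignError):
            tl.factorial_anova(np.arange(4.0), factors)


class TestSimpleEffects:
    def test_hand_computed(self, toy_2x2):
        y, factors = toy_2x2
        tab = tl.simple_effects(y, factors, target="A", within="B")
        b0 = tab[tab["within_level"] == "b0"].iloc[0]
        assert b0["F"] == pytest.approx(8.0)
        assert (b0["df_num"], b0["df_den"]) == (1, 4.0)
        assert b0["diff"] == pytest.approx(4.0)

    def test_identical_means_give_zero(self):
        factors = pd.DataFrame(
            {"A": ["a0", "a1"] * 4, "B": ["b0"] * 4 + ["b1"] * 4}
        )
        y = np.array([2.0, 2.0, 3.0, 3.0, 1.0, 5.0, 1.0, 5.0])
        tab = tl.simple_effects(y, factors, target="A", within="B")
        assert tab[tab["within_level"] == "b0"]["F"].iloc[0] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_target_equal_within(self, toy_2x2):
        y, factors = toy_2x2
        with pytest.raises(ValueError):
            tl.simple_effects(y, factors, target="A", within="A")


class TestScalarTests:
    def test_one_sample_t(self):
        res = tl.one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2

    def test_one_sample_t_null(self):
        res = tl.one_sample_t([1.0, 3.0], 2.0)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_one_sample_t_errors(self):
        with pytest.raises(DegenerateInputError):
            tl.one_sample_t([1.0])
        with pytest.raises(DegenerateInputError):
            tl.one_sample_t([2.0, 2.0, 2.0])

    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [3, 5, 7, 9], 1.0),
            ([1, 2, 3], [-1, -2, -3], -1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),
        ],
    )
    def test_pearson(self, x, y, expected):
        assert tl.pearson_r(x, y).statistic == pytest.approx(expected)

    def test_pearson_errors(self):
        with pytest.raises(DegenerateInputError):
            tl.pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(DegenerateInputError):
            tl.pearson_r([1, 2], [1, 2])


class TestFisherZ:
    def test_reported_comparison(self):
        # the age/consolidation correlations of the two experience groups
        res = tl.fisher_z_compare(-0.448, 64, -0.167, 64, tail="one")
        assert round(res.statistic, 2) == -1.73
        assert round(res.p, 3) == 0.042

    def test_equal_correlations(self):
        res = tl.fisher_z_compare(0.3, 50, 0.3, 50, tail="one")
        assert res.statistic == 0.0
        assert res.p == 0.5

    @given(
        r1=st.floats(-0.95, 0.95), r2=st.floats(-0.95, 0.95),
        n1=st.integers(4, 500), n2=st.integers(4, 500),
    )
    def test_antisymmetry_and_valid_p(self, r1, r2, n1, n2):
        a = tl.fisher_z_compare(r1, n1, r2, n2)
        b = tl.fisher_z_compare(r2, n2, r1, n1)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
        assert 0.0 <= a.p <= 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tl.fisher_z_compare(1.0, 10, 0.5, 10)
        with pytest.raises(ValueError):
            tl.fisher_z_compare(0.5, 3, 0.5, 10)


class TestCurveParamAnovas:
    def test_constructed_separation(self):
        factors = tl.generate_design(2, seed=8)
        players = (factors["piano"] == "player").to_numpy()
        estimates = pd.DataFrame(
            {
                "subject_id": factors["subject_id"],
                "I": np.where(players, 15.0, 8.0)
                + np.random.default_rng(1).normal(0, 0.3, len(factors)),
                "C": 8.0,
                "R": 0.6,
            }
        )
        tables = tl.curve_param_anovas(estimates, factors)
        assert set(tables) == {"I", "R", "improvement"}
        tab_I = tables["I"].set_index("effect")
        assert tab_I.loc["piano", "F"] > 100
        # R constant: its table has zero effect SS throughout
        tab_R = tables["R"].set_index("effect")
        assert np.allclose(tab_R.drop("Residual")["ss"], 0.0, atol=1e-12)

    def test_df_den_117_per_table(self, main_cohort):
        factors, _, truth = main_cohort
        rng = np.random.default_rng(0)
        estimates = pd.DataFrame(
            {
                "subject_id": factors["subject_id"],
                "I": rng.normal(10, 2, len(factors)),
                "C": rng.normal(8, 2, len(factors)),
                "R": rng.uniform(0.3, 0.8, len(factors)),
            }
        )
        for tab in tl.curve_param_anovas(estimates, factors).values():
            effects = tab[tab["effect"] != "Residual"]
            assert (effects["df_den"] == 117).all()

    def test_missing_subject(self, toy_2x2):
        factors = tl.generate_design(1, seed=0)
        estimates = pd.DataFrame(
            {"subject_id": factors["subject_id"][:-1], "I": 1.0, "C": 1.0,
             "R": 0.5}
        )
        with pytest.raises(KeyError):
            tl.curve_param_anovas(estimates, factors)
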