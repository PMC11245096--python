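import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habprof.synthetic_data import generate_genome_table
from habprof.varpart import (
    AnovaTable,
    TermStats,
    binary_trait_screen,
    oneway_anova,
    percent_contribution,
    screen_features,
    tukey_hsd,
    twoway_anova_sequential,
    within_lineage_tests,
)

from conftest import make_genome_sim_config


# --- independent oracle: explicit orthogonal projections onto nested spaces


def _proj(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def seq_ss_oracle(y, a, b):
    """Sequential SS via hat-matrix differences (treatment-coded designs)."""
    y = np.asarray(y, float)
    n = len(y)
    da = pd.get_dummies(pd.Series(a), drop_first=True).to_numpy(float)
    db = pd.get_dummies(pd.Series(b), drop_first=True).to_numpy(float)
    dab = pd.get_dummies(pd.Series([f"{x}|{z}" for x, z in zip(a, b)]),
                         drop_first=False).to_numpy(float)
    designs = [
        np.ones((n, 1)),
        np.column_stack([np.ones(n), da]),
        np.column_stack([np.ones(n), da, db]),
        np.column_stack([np.ones(n), dab]),  # cell-mean space = full interaction space
    ]
    hats = [_proj(x) for x in designs]
    ss = [float(y @ (hats[i + 1] - hats[i]) @ y) for i in range(3)]
    ss_res = float(y @ (np.eye(n) - hats[3]) @ y)
    dfs = [int(round(np.trace(hats[i + 1] - hats[i]))) for i in range(3)]
    df_res = n - int(round(np.trace(hats[3])))
    return ss + [ss_res], dfs + [df_res]


def _random_design(rng, n):
    a = rng.choice(["a1", "a2", "a3"], size=n)
    b = rng.choice(["b1", "b2"], size=n)
    # ensure both factors have >=2 levels
    a[0], a[1] = "a1", "a2"
    b[0], b[1] = "b1", "b2"
    y = rng.normal(size=n)
    return y, a, b


class TestTwowayAnova:
    def test_pure_a_effect_closed_form(self):
        y = [1, 1, 1, 1, 3, 3, 3, 3]
        a = ["A1"] * 4 + ["A2"] * 4
        b = ["B1", "B2"] * 4
        tab = twoway_anova_sequential(y, a, b)
        assert tab.term("A").ss == pytest.approx(8.0)
        assert tab.term("B").ss == pytest.approx(0.0, abs=1e-12)
        assert tab.term("A:B").ss == pytest.approx(0.0, abs=1e-12)
        assert tab.term("residual").ss == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_undefined(self):
        y = [2.0] * 8
        a = ["A1"] * 4 + ["A2"] * 4
        b = ["B1", "B2"] * 4
        tab = twoway_anova_sequential(y, a, b)
        for t in tab.terms:
            assert t.ss == pytest.approx(0.0, abs=1e-12)
            assert t.f is None and t.p is None

    def test_single_level_factor_errors(self):
        with pytest.raises(ValueError, match="2 levels"):
            twoway_anova_sequential([1, 2, 3], ["A"] * 3, ["B1", "B2", "B1"])

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            twoway_anova_sequential([1, 2], ["A", "B", "A"], ["x", "y", "x"])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_projection_oracle_unbalanced(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 51))
        y, a, b = _random_design(rng, n)
        tab = twoway_anova_sequential(y, a, b)
        ss_oracle, df_oracle = seq_ss_oracle(y, a, b)
        ss_impl = [t.ss for t in tab.terms]
        df_impl = [t.df for t in tab.terms]
        total = sum(ss_oracle)
        for s_i, s_o in zip(ss_impl, ss_oracle):
            assert abs(s_i - s_o) <= 1e-8 * max(total, 1.0)
        assert df_impl == df_oracle

    def test_matches_statsmodels_type1(self):
        # second independent route on a full-rank unbalanced design
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(99)
        y, a, b = _random_design(rng, 40)
        df = pd.DataFrame({"y": y, "a": a, "b": b})
        fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
        sm_tab = sm.stats.anova_lm(fit, typ=1)
        tab = twoway_anova_sequential(y, a, b)
        for impl, name in zip(tab.terms, ["C(a)", "C(b)", "C(a):C(b)", "Residual"]):
            assert impl.ss == pytest.approx(sm_tab.loc[name, "sum_sq"], rel=1e-8)
            assert impl.df == int(sm_tab.loc[name, "df"])
        for impl, name in zip(tab.terms[:3], ["C(a)", "C(b)", "C(a):C(b)"]):
            assert impl.p == pytest.approx(sm_tab.loc[name, "PR(>F)"], rel=1e-8)

    def test_ss_additivity(self):
        rng = np.random.default_rng(5)
        y, a, b = _random_design(rng, 37)
        tab = twoway_anova_sequential(y, a, b)
        ss_total = float(np.sum((y - np.mean(y)) ** 2))
        assert tab.total_ss == pytest.approx(ss_total, rel=1e-8)

    def test_order_sensitive_on_unbalanced_invariant_on_balanced(self):
        rng = np.random.default_rng(11)
        # unbalanced: correlated factors
        y, a, b = _random_design(rng, 45)
        t_ab = twoway_anova_sequential(y, a, b, factor_names=("A", "B"))
        t_ba = twoway_anova_sequential(y, b, a, factor_names=("B", "A"))
        assert t_ab.term("A").ss != pytest.approx(t_ba.term("A").ss)
        # balanced: full crossing, equal cell sizes
        a_bal = np.repeat(["a1", "a2"], 10)
        b_bal = np.tile(["b1", "b2"], 10)
        y_bal = rng.normal(size=20)
        t1 = twoway_anova_sequential(y_bal, a_bal, b_bal, factor_names=("A", "B"))
        t2 = twoway_anova_sequential(y_bal, b_bal, a_bal, factor_names=("B", "A"))
        assert t1.term("A").ss == pytest.approx(t2.term("A").ss, rel=1e-10)
        assert t1.term("B").ss == pytest.approx(t2.term("B").ss, rel=1e-10)

    def test_empty_cells_reduce_interaction_df(self):
        # 2x2 with one empty cell: interaction is inestimable
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        a = ["a1", "a1", "a1", "a2", "a2", "a2"]
        b = ["b1", "b1", "b2", "b2", "b2", "b2"]
        tab = twoway_anova_sequential(y, a, b)
        assert tab.term("A:B").df == 0


class TestPercentContribution:
    def _table(self, ss):
        terms = tuple(
            TermStats(name, 1, s, None, None)
            for name, s in zip(["A", "B", "A:B", "residual"], ss)
        )
        return AnovaTable(response="y", terms=terms)

    def test_single_source(self):
        t = percent_contribution(self._table([8.0, 0.0, 0.0, 0.0]))
        assert t.pct_contribution["A"] == pytest.approx(100.0)
        assert t.pct_contribution["B"] == pytest.approx(0.0)

    def test_shares_include_residual(self):
        t = percent_contribution(self._table([45.0, 45.0, 5.0, 5.0]))
        assert t.pct_contribution["A"] == pytest.approx(45.0)
        assert sum(t.pct_contribution.values()) == pytest.approx(100.0)

    def test_zero_total_undefined(self):
        t = percent_contribution(self._table([0.0, 0.0, 0.0, 0.0]))
        assert all(math.isnan(v) for v in t.pct_contribution.values())

    @pytest.mark.parametrize("share", [0.10, 0.25, 0.40])
    def test_generating_share_recovered(self, share):
        # variance bookkeeping of the generating model, 5 seeds per share
        # (the 20-seed version runs in the acceptance suite)
        d = math.sqrt(1.5 * share / (1 - share))
        recovered = []
        for seed in range(5):
            cfg = make_genome_sim_config(seed=seed, n_per_cell=100, class_spread=d)
            genomes, _ = generate_genome_table(cfg)
            cls = [lin.split("c__")[1] for lin in genomes["lineage"]]
            tab = twoway_anova_sequential(
                genomes["x"], cls, genomes["habitat"], factor_names=("class", "habitat")
            )
            recovered.append(tab.pct_contribution["class"])
        assert np.mean(recovered) == pytest.approx(100 * share, abs=5.0)


class TestTukey:
    def test_identical_groups(self):
        res = tukey_hsd([1, 2, 3, 1, 2, 3], ["g1"] * 3 + ["g2"] * 3)
        pair = res.pairs[0]
        assert pair.mean_difference == pytest.approx(0.0)
        assert pair.p_adj == pytest.approx(1.0, abs=1e-9)

    def test_two_groups_equals_pooled_ttest(self):
        rng = np.random.default_rng(1)
        y1, y2 = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        res = tukey_hsd(np.concatenate([y1, y2]), ["a"] * 12 + ["b"] * 9)
        t_p = stats.ttest_ind(y1, y2, equal_var=True).pvalue
        assert res.pairs[0].p_adj == pytest.approx(t_p, abs=1e-6)

    def test_three_unbalanced_groups_vs_scipy_oracle(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 8), rng.normal(1, 1, 5), rng.normal(0.5, 1, 12)]
        y = np.concatenate(groups)
        g = ["g0"] * 8 + ["g1"] * 5 + ["g2"] * 12
        res = tukey_hsd(y, g, alpha=0.05)
        oracle = stats.tukey_hsd(*groups)
        ci = oracle.confidence_interval(0.95)
        idx = {("g0", "g1"): (0, 1), ("g0", "g2"): (0, 2), ("g1", "g2"): (1, 2)}
        for pair in res.pairs:
            i, j = idx[(pair.group_a, pair.group_b)]
            assert pair.p_adj == pytest.approx(oracle.pvalue[i, j], abs=1e-8)
            assert pair.mean_difference == pytest.approx(oracle.statistic[i, j], rel=1e-10)
            assert pair.ci_low == pytest.approx(ci.low[i, j], rel=1e-6)
            assert pair.ci_high == pytest.approx(ci.high[i, j], rel=1e-6)

    def test_ci_brackets_difference(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        g = rng.choice(["a", "b", "c"], size=30)
        g[:3] = ["a", "b", "c"]
        for pair in tukey_hsd(y, g).pairs:
            assert pair.ci_low <= pair.mean_difference <= pair.ci_high
            assert 0.0 <= pair.p_adj <= 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            tukey_hsd([1.0, 2.0], ["a", "a"])

    def test_zero_variance_degenerate(self):
        res = tukey_hsd([1, 1, 2, 2], ["a", "a", "b", "b"])
        pair = res.pairs[0]
        assert pair.degenerate and pair.p_adj == 0.0


class TestScreens:
    def test_pure_class_effect_flags_class_only(self):
        cfg = make_genome_sim_config(seed=0, n_per_cell=50, class_spread=3.0, noise_sd=1.0)
        genomes, _ = generate_genome_table(cfg)
        res = screen_features(genomes, ["x"], grouping="by-class")[0]
        assert "lineage" in res.significant_terms
        assert "habitat" not in res.significant_terms
        assert "lineage" in res.tukey

    def test_missing_feature_named(self):
        cfg = make_genome_sim_config(n_per_cell=5)
        genomes, _ = generate_genome_table(cfg)
        with pytest.raises(ValueError, match="nope"):
            screen_features(genomes, ["nope"])

    def test_empty_feature_list(self):
        cfg = make_genome_sim_config(n_per_cell=5)
        genomes, _ = generate_genome_table(cfg)
        assert screen_features(genomes, []) == []

    def test_spl_nspl_grouping(self):
        cfg = make_genome_sim_config(seed=1, n_per_cell=40, class_spread=2.0)
        genomes, _ = generate_genome_table(cfg)
        pref = {"Alpha": "SPL", "Beta": "NSPL"}  # Gamma dropped
        res = screen_features(
            genomes, ["x"], grouping="SPL-vs-NSPL", preference_map=pref
        )[0]
        assert res.anova.term("lineage").df == 1

    def test_binary_trait_class_effect(self):
        rng = np.random.default_rng(4)
        n = 600
        cls = np.repeat(["SPLc", "NSPLc"], n // 2)
        hab = np.tile(["soil", "non-soil"], n // 2)
        p = np.where(cls == "SPLc", 0.9, 0.1)
        traits = pd.DataFrame({"t1": (rng.random(n) < p).astype(int)})
        res = binary_trait_screen(traits, cls, hab)[0]
        assert "lineage" in res.significant_terms

    def test_constant_trait_skipped(self):
        traits = pd.DataFrame({"t1": [1, 1, 1, 1]})
        res = binary_trait_screen(traits, ["a", "a", "b", "b"], ["x", "y", "x", "y"])[0]
        assert res.skipped_constant and res.significant_terms == ()

    def test_nonbinary_trait_rejected(self):
        traits = pd.DataFrame({"t1": [0, 1, 2, 1]})
        with pytest.raises(ValueError, match="0 or 1"):
            binary_trait_screen(traits, ["a", "a", "b", "b"], ["x", "y", "x", "y"])

    def test_null_permutations_rarely_pass_screen(self):
        rng = np.random.default_rng(6)
        cfg = make_genome_sim_config(seed=2, n_per_cell=20, class_spread=0.0)
        genomes, _ = generate_genome_table(cfg)
        cls = np.array([lin.split("c__")[1] for lin in genomes["lineage"]])
        hits = 0
        for _ in range(50):
            perm = rng.permutation(len(genomes))
            tab = twoway_anova_sequential(
                genomes["x"].to_numpy(), cls[perm], genomes["habitat"].to_numpy()[perm]
            )
            hits += sum(
                1 for t in tab.terms[:3] if t.p is not None and t.p < 1e-5
            )
        assert hits == 0  # 150 null tests at alpha=1e-5


class TestWithinLineage:
    def test_soil_offset_detected(self):
        cfg = make_genome_sim_config(seed=3, n_per_cell=60, habitat_shift=2.0, noise_sd=1.0)
        genomes, _ = generate_genome_table(cfg)
        res = within_lineage_tests(genomes, "Alpha", ["x"])[0]
        assert res.significant and not res.indeterminate

    def test_null_not_flagged(self):
        cfg = make_genome_sim_config(seed=4, n_per_cell=60, habitat_shift=0.0)
        genomes, _ = generate_genome_table(cfg)
        res = within_lineage_tests(genomes, "Alpha", ["x"])[0]
        assert not res.significant

    def test_one_side_empty_indeterminate(self):
        cfg = make_genome_sim_config(n_per_cell=10)
        genomes, _ = generate_genome_table(cfg)
        genomes = genomes[genomes["habitat"] == "marine"]
        res = within_lineage_tests(genomes, "Alpha", ["x"])[0]
        assert res.indeterminate and res.anova is None


class TestOnewayAnova:
    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=30)
        g = np.array(["a"] * 10 + ["b"] * 12 + ["c"] * 8)
        tab = oneway_anova(y, g)
        f, p = stats.f_oneway(y[g == "a"], y[g == "b"], y[g == "c"])
        assert tab.term("group").f == pytest.approx(f, rel=1e-10)
        assert tab.term("group").p == pytest.approx(p, rel=1e-10)
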