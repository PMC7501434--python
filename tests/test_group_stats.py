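import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokefc import group_stats, synth


from oracles import _oracle_mixed_anova


class TestMixedAnova:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle_on_random_instances(self, seed):
        r = np.random.default_rng(seed)
        n1, n2 = int(r.integers(2, 5)), int(r.integers(2, 5))
        Y = r.normal(size=(n1 + n2, 3)) + r.normal(size=3)
        groups = ["patient"] * n1 + ["control"] * n2
        res = group_stats.mixed_anova(Y, groups)
        Fg, Fc, Fi = _oracle_mixed_anova(Y, groups)
        assert res.F_group == pytest.approx(Fg, abs=1e-8)
        assert res.F_condition == pytest.approx(Fc, abs=1e-8)
        assert res.F_interaction == pytest.approx(Fi, abs=1e-8)

    def test_matches_pingouin_on_balanced_design(self):
        pg = pytest.importorskip("pingouin")
        r = np.random.default_rng(7)
        n = 9
        Y = r.normal(size=(2 * n, 3)) + np.array([0.0, 0.4, 0.8])
        Y[:n] += 0.5
        groups = np.array(["patient"] * n + ["control"] * n)
        res = group_stats.mixed_anova(Y, groups)
        df = pd.DataFrame({
            "y": Y.ravel(),
            "subject": np.repeat(np.arange(2 * n), 3),
            "cond": np.tile(list("abc"), 2 * n),
            "group": np.repeat(groups, 3),
        })
        aov = pg.mixed_anova(data=df, dv="y", within="cond", between="group",
                             subject="subject").set_index("Source")
        assert res.F_group == pytest.approx(aov.loc["group", "F"], rel=1e-9)
        assert res.F_condition == pytest.approx(aov.loc["cond", "F"], rel=1e-9)
        assert res.F_interaction == pytest.approx(aov.loc["Interaction", "F"], rel=1e-9)

    def test_type3_numerators_match_statsmodels_when_unbalanced(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        r = np.random.default_rng(11)
        n1, n2 = 5, 11
        Y = r.normal(size=(n1 + n2, 3)) + np.array([0.0, 0.5, 1.0])
        Y[:n1] += 0.7
        groups = np.array(["patient"] * n1 + ["control"] * n2)
        res = group_stats.mixed_anova(Y, groups)
        df = pd.DataFrame({
            "y": Y.ravel(),
            "cond": np.tile(list("abc"), n1 + n2),
            "group": np.repeat(groups, 3),
        })
        a3 = anova_lm(smf.ols("y ~ C(group, Sum)*C(cond, Sum)", data=df).fit(), typ=3)
        # reconstruct numerator SS from our F and the error strata
        m = Y.mean(axis=1)
        gm = {g: m[groups == g].mean() for g in ("patient", "control")}
        ms_subj = 3 * sum((m[i] - gm[groups[i]]) ** 2 for i in range(n1 + n2)) / (n1 + n2 - 2)
        ss_group = res.F_group * ms_subj
        assert ss_group == pytest.approx(a3.loc["C(group, Sum)", "sum_sq"], rel=1e-9)

    def test_constant_data_flagged_degenerate(self):
        Y = np.full((6, 3), 4.2)
        res = group_stats.mixed_anova(Y, ["patient"] * 3 + ["control"] * 3)
        assert res.degenerate
        assert res.F_group == 0.0 and res.F_condition == 0.0 and res.F_interaction == 0.0

    def test_pure_condition_shift_yields_large_condition_f_only(self):
        r = np.random.default_rng(5)
        n = 50
        Y = r.normal(size=(2 * n, 3)) + np.array([0.0, 1.0, 2.0])
        groups = ["patient"] * n + ["control"] * n
        res = group_stats.mixed_anova(Y, groups)
        assert res.F_condition > 50
        assert res.F_condition > 10 * res.F_interaction
        assert res.p_interaction > 0.01

    def test_balanced_f_invariant_to_constant_shift(self):
        r = np.random.default_rng(6)
        Y = r.normal(size=(12, 3))
        groups = ["patient"] * 6 + ["control"] * 6
        a = group_stats.mixed_anova(Y, groups)
        b = group_stats.mixed_anova(Y + 17.3, groups)
        assert a.F_group == pytest.approx(b.F_group, rel=1e-9)
        assert a.F_condition == pytest.approx(b.F_condition, rel=1e-9)
        assert a.F_interaction == pytest.approx(b.F_interaction, rel=1e-9)

    def test_dfs_consistent_with_design(self):
        r = np.random.default_rng(8)
        Y = r.normal(size=(10, 3))
        res = group_stats.mixed_anova(Y, ["patient"] * 4 + ["control"] * 6)
        assert res.df_group == (1, 8)
        assert res.df_condition == (2, 16)
        assert res.df_interaction == (2, 16)

    def test_missing_cells_rejected(self):
        Y = np.ones((4, 3))
        Y[0, 1] = np.nan
        with pytest.raises(ValueError):
            group_stats.mixed_anova(Y, ["patient"] * 2 + ["control"] * 2)

    def test_gg_correction_inflates_p_under_sphericity_violation(self):
        r = np.random.default_rng(9)
        # heteroscedastic conditions (sphericity violated) + real condition effect
        Y = r.normal(size=(14, 3)) * np.array([0.2, 1.0, 3.0]) + np.array([0.0, 1.0, 2.0])
        groups = ["patient"] * 7 + ["control"] * 7
        plain = group_stats.mixed_anova(Y, groups)
        corr = group_stats.mixed_anova(Y, groups, gg=True)
        assert plain.F_condition > 1  # correction is only conservative above 1
        assert corr.p_condition >= plain.p_condition - 1e-12
        assert corr.F_condition == plain.F_condition


class TestFdrBH:
    def test_hand_worked_step_up(self):
        flags = group_stats.fdr_bh([0.001, 0.01, 0.02, 0.9], q=0.05)
        # step-up: p(3)=0.02 <= 3*0.05/4 -> reject first three
        assert flags.tolist() == [True, True, True, False]

    def test_all_ones_and_all_zeros(self):
        assert group_stats.fdr_bh([1.0] * 5).sum() == 0
        assert group_stats.fdr_bh([0.0] * 5).sum() == 5

    def test_empty_input(self):
        assert group_stats.fdr_bh([]).size == 0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
           st.floats(min_value=0.01, max_value=0.2), st.floats(min_value=0.2, max_value=0.99))
    def test_rejections_monotone_in_q(self, ps, q1, q2):
        small = group_stats.fdr_bh(ps, q=q1)
        large = group_stats.fdr_bh(ps, q=q2)
        assert np.all(large[small])  # everything rejected at q1 is rejected at q2


class TestSDSA:
    def test_constant_column_gives_zero(self):
        ts = np.column_stack([np.full(100, 3.0), np.arange(100.0)])
        assert group_stats.compute_sdsa(ts)[0] == 0.0

    def test_sine_amplitude_two_gives_rms(self):
        t = np.arange(1000)
        ts = (2.0 * np.sin(2 * np.pi * t / 1000))[:, None]
        assert group_stats.compute_sdsa(ts)[0] == pytest.approx(2 / np.sqrt(2), abs=0.01)

    def test_unit_gaussian_sd_near_one(self):
        r = np.random.default_rng(12)
        ts = r.normal(size=(10_000, 1))
        assert 0.97 <= group_stats.compute_sdsa(ts)[0] <= 1.03

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            group_stats.compute_sdsa(np.ones((1, 3)))

    def test_sdsa_table_reflects_node_scale_ground_truth(self, small_cohort):
        model, cohort = small_cohort
        table = group_stats.sdsa_table(cohort)
        assert len(table) == 14 * 3
        # node scales are 1 except task-reduced nodes; mean SDSA tracks them
        sc = model.node_scale[("control", "L2")]
        sub = table[table.condition == "L2"].filter(like="node_").mean()
        assert np.corrcoef(sub.to_numpy(), sc)[0, 1] > 0.5 or np.allclose(sc, sc[0])


class TestTables:
    def test_edgewise_single_edge_equals_mixed_anova(self):
        r = np.random.default_rng(13)
        n = 8
        rows = []
        Y = r.normal(size=(n, 3))
        for s in range(n):
            for ci, cond in enumerate(synth.CONDITIONS):
                rows.append({"subject_id": f"s{s}", "group": "patient" if s < 4 else "control",
                             "condition": cond, "edge_1_2": Y[s, ci]})
        table = pd.DataFrame(rows)
        stats_table = group_stats.edgewise_anova(table)
        res = group_stats.mixed_anova(Y, ["patient"] * 4 + ["control"] * 4)
        assert len(stats_table) == 1
        assert stats_table.loc[0, "F_group"] == pytest.approx(res.F_group, rel=1e-12)
        assert stats_table.loc[0, "F_condition"] == pytest.approx(res.F_condition, rel=1e-12)
        assert not stats_table.loc[0, "fdr_group"] or stats_table.loc[0, "sig_group"]

    def test_missing_condition_rejected(self):
        table = pd.DataFrame({
            "subject_id": ["s0", "s0", "s0", "s1", "s1"],
            "group": ["patient"] * 3 + ["control"] * 2,
            "condition": ["rest", "L1", "L2", "rest", "L1"],
            "edge_1_2": np.arange(5.0),
        })
        with pytest.raises(ValueError, match="missing"):
            group_stats.edgewise_anova(table)

    def test_nodewise_sdsa_detects_task_modulated_nodes(self):
        spec = synth.EffectSpec(sdsa_nodes=[(2, {"rest": 1.0, "L1": 0.8, "L2": 0.8})])
        model = synth.make_ground_truth(4, 0.1, spec, seed=14, base_rho=(0.0, 0.0))
        cohort = synth.generate_cohort(model, 25, 25,
                                       frames={"rest": 150, "L1": 150, "L2": 150}, seed=14)
        sd = group_stats.sdsa_table(cohort)
        res = group_stats.nodewise_sdsa_anova(sd)
        assert bool(res.loc[res.node == "node_2", "fdr_condition"].iloc[0])
        assert res.loc[res.node == "node_2", "F_condition"].iloc[0] == res["F_condition"].max()


class TestSummaryTests:
    def test_welch_identical_summaries_give_zero(self):
        t, df, p = group_stats.welch_t_from_summary((5.0, 1.0, 30), (5.0, 1.0, 30))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_zero_variance_equal_means_convention(self):
        t, _, p = group_stats.welch_t_from_summary((2.0, 0.0, 10), (2.0, 0.0, 10))
        assert t == 0.0 and p == 1.0

    def test_welch_agrees_with_scipy_from_stats(self):
        from scipy import stats as sps
        t, df, p = group_stats.welch_t_from_summary((77.7, 24.9, 44), (84.0, 24.0, 100))
        ref = sps.ttest_ind_from_stats(77.7, 24.9, 44, 84.0, 24.0, 100, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_chi2_hand_computation_diagonal_table(self):
        x2, df, p = group_stats.chi2_independence([[10, 0], [0, 10]])
        assert x2 == pytest.approx(20.0)
        assert df == 1

    def test_chi2_equal_proportions_zero(self):
        x2, _, p = group_stats.chi2_independence([[20, 20], [30, 30]])
        assert x2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chi2_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            group_stats.chi2_independence([[0, 0], [5, 5]])
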