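"""Mixed ANOVA/ANCOVA against brute-force sums-of-squares oracles; t-tests; JZS BF."""

import numpy as np
import pandas as pd
import pytest

import cdakit.stats as st


def brute_force_mixed_anova(Y, group):
    """Independent split-plot oracle: classical balanced SS formulas, explicit loops."""
    Y = np.asarray(Y, float)
    group = np.asarray(group)
    n, k = Y.shape
    levels = sorted(set(group))
    gm = Y.mean()
    subj_means = Y.mean(axis=1)
    ss_subj = k * np.sum((subj_means - gm) ** 2)
    ss_group = k * sum((group == g).sum() * (Y[group == g].mean() - gm) ** 2
                       for g in levels)
    ss_bs_err = ss_subj - ss_group
    ss_cond = n * np.sum((Y.mean(axis=0) - gm) ** 2)
    ss_cells = sum((group == g).sum() * np.sum((Y[group == g].mean(axis=0) - gm) ** 2)
                   for g in levels)
    ss_int = ss_cells - ss_group - ss_cond
    ss_total = np.sum((Y - gm) ** 2)
    ss_ws_err = ss_total - ss_subj - ss_cond - ss_int
    gsizes = [(group == g).sum() for g in levels]
    df_bs = n - len(levels)
    df_ws = (k - 1) * df_bs
    return {
        "group": (ss_group / (len(levels) - 1)) / (ss_bs_err / df_bs),
        "condition": (ss_cond / (k - 1)) / (ss_ws_err / df_ws),
        "condition*group": (ss_int / ((k - 1) * (len(levels) - 1))) / (ss_ws_err / df_ws),
    }


class TestMixedAnova:
    def test_identical_values_give_zero_f(self):
        Y = np.full((10, 3), 4.2)
        res = st.rm_anova_mixed(Y, ["a"] * 5 + ["b"] * 5)
        for r in res.values():
            assert r.statistic == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_ss_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_per = int(rng.integers(4, 15))
        Y = rng.normal(rng.normal(0, 1, 3), 1.0, (2 * n_per, 3))
        grp = ["a"] * n_per + ["b"] * n_per
        mine = st.rm_anova_mixed(Y, grp)
        oracle = brute_force_mixed_anova(Y, grp)
        for eff, f in oracle.items():
            assert mine[eff].statistic == pytest.approx(f, abs=1e-8, rel=1e-8)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        Y = rng.normal(0, 1, (16, 3))
        grp = ["a"] * 8 + ["b"] * 8
        mine = st.rm_anova_mixed(Y, grp)
        long = pd.DataFrame({
            "y": Y.ravel(), "cond": ["c1", "c2", "c3"] * 16,
            "subj": np.repeat(np.arange(16), 3), "grp": np.repeat(grp, 3)})
        ref = pg.mixed_anova(long, dv="y", within="cond", subject="subj",
                             between="grp").set_index("Source")
        assert mine["group"].statistic == pytest.approx(ref.loc["grp", "F"], rel=1e-9)
        assert mine["condition"].statistic == pytest.approx(ref.loc["cond", "F"], rel=1e-9)
        assert mine["condition*group"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)
        assert mine["condition*group"].effect_size == pytest.approx(
            ref.loc["Interaction", "np2"], rel=1e-9)

    def test_study_design_dfs(self):
        rng = np.random.default_rng(0)
        res = st.rm_anova_mixed(rng.normal(0, 1, (36, 3)), ["a"] * 18 + ["b"] * 18)
        assert res["condition"].df == (2.0, 68.0)
        assert res["condition*group"].df == (2.0, 68.0)
        assert res["group"].df == (1.0, 34.0)

    def test_missing_cell_rejected(self):
        Y = np.ones((6, 3))
        Y[0, 1] = np.nan
        with pytest.raises(ValueError, match="[Mm]issing"):
            st.rm_anova_mixed(Y, ["a"] * 3 + ["b"] * 3)

    def test_gg_correction_reported(self):
        rng = np.random.default_rng(5)
        res = st.rm_anova_mixed(rng.normal(0, 1, (12, 3)), ["a"] * 6 + ["b"] * 6,
                                sphericity_correction="gg")
        from scipy import stats as sps

        r = res["condition"]
        eps = r.notes["gg_epsilon"]
        assert 0.5 <= eps <= 1.0
        assert r.notes["gg_df"] == pytest.approx((2 * eps, 20 * eps))
        assert r.notes["gg_p"] == pytest.approx(
            float(sps.f.sf(r.statistic, 2 * eps, 20 * eps)))


class TestTwoWithinAnova:
    def test_matches_brute_force_on_balanced_design(self):
        """Each within stratum equals the explicit derived-scores decomposition."""
        rng = np.random.default_rng(21)
        n_per, a, b = 8, 3, 2
        Y = rng.normal(0, 1, (2 * n_per, a * b))
        grp = ["x"] * n_per + ["y"] * n_per
        mine = st.rm_anova_two_within(Y, grp, ("A", "B"), (a, b))
        cells = Y.reshape(-1, a, b)
        # A stratum: one-within oracle on b-averaged scores, SS scaled by b
        oracle_A = brute_force_mixed_anova(cells.mean(axis=2), grp)
        assert mine["A"].statistic == pytest.approx(oracle_A["condition"], rel=1e-8)
        assert mine["A*group"].statistic == pytest.approx(
            oracle_A["condition*group"], rel=1e-8)
        oracle_B = brute_force_mixed_anova(cells.mean(axis=1), grp)
        assert mine["B"].statistic == pytest.approx(oracle_B["condition"], rel=1e-8)
        # A x B stratum: double-centred interaction scores per subject
        Z = (cells - cells.mean(2, keepdims=True) - cells.mean(1, keepdims=True)
             + cells.mean((1, 2), keepdims=True))
        grp_arr = np.asarray(grp)
        gm_z = Z.mean(axis=0)
        ss_ab = 2 * n_per * np.sum(gm_z ** 2)
        ss_cells = sum(n_per * np.sum(Z[grp_arr == g].mean(axis=0) ** 2) for g in "xy")
        ss_abg = ss_cells - ss_ab
        ss_err = np.sum(Z ** 2) - ss_cells
        df_eff, df_err = (a - 1) * (b - 1), (a - 1) * (b - 1) * (2 * n_per - 2)
        assert mine["A*B"].statistic == pytest.approx(
            (ss_ab / df_eff) / (ss_err / df_err), rel=1e-8)
        assert mine["A*B*group"].statistic == pytest.approx(
            (ss_abg / df_eff) / (ss_err / df_err), rel=1e-8)

    def test_rejection_design_dfs(self):
        rng = np.random.default_rng(2)
        res = st.rm_anova_two_within(rng.normal(0, 1, (36, 6)), ["a"] * 18 + ["b"] * 18)
        assert res["condition"].df == (2.0, 68.0)
        assert res["cue_side"].df == (1.0, 34.0)
        assert res["condition*cue_side"].df == (2.0, 68.0)


class TestAncova:
    def test_interaction_df_at_study_size(self):
        rng = np.random.default_rng(3)
        res = st.ancova_mixed(rng.normal(0, 1, (36, 3)), ["a"] * 18 + ["b"] * 18,
                              rng.normal(0, 1, 36))
        assert res["condition*group"].df == (2.0, 66.0)
        assert res["group"].df == (1.0, 33.0)

    def test_orthogonal_covariate_leaves_within_ss_unchanged(self):
        """A covariate orthogonalized against the design changes only error df."""
        rng = np.random.default_rng(4)
        n = 20
        Y = rng.normal(0, 1, (n, 3))
        grp = ["a"] * 10 + ["b"] * 10
        from scipy.linalg import helmert, lstsq

        C = helmert(3, full=False)
        G = np.where(np.asarray(grp) == "a", 1.0, -1.0)
        X = np.column_stack([np.ones(n), G, Y.mean(1), Y @ C.T])
        cov = rng.normal(0, 1, n)
        cov = cov - X @ lstsq(X, cov)[0]
        anc = st.ancova_mixed(Y, grp, cov)
        rm = st.rm_anova_mixed(Y, grp)
        for eff in ("condition", "condition*group"):
            assert anc[eff].notes["ss_effect"] == pytest.approx(
                rm[eff].notes["ss_effect"], rel=1e-8)
            assert anc[eff].notes["ss_error"] == pytest.approx(
                rm[eff].notes["ss_error"], rel=1e-8)
            # same SS; the error mean square is spread over one fewer df per
            # contrast (36 -> 34), so F shrinks by exactly that ratio
            assert anc[eff].statistic == pytest.approx(
                rm[eff].statistic * 34 / 36, rel=1e-8)

    def test_group_indicator_covariate_is_singular(self):
        Y = np.random.default_rng(5).normal(0, 1, (10, 3))
        grp = ["a"] * 5 + ["b"] * 5
        cov = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError, match="singular|collinear"):
            st.ancova_mixed(Y, grp, cov)

    def test_constant_covariate_rejected(self):
        Y = np.random.default_rng(6).normal(0, 1, (10, 3))
        with pytest.raises(ValueError, match="constant"):
            st.ancova_mixed(Y, ["a"] * 5 + ["b"] * 5, np.ones(10))


class TestTTests:
    def test_identical_groups_give_zero_t(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = st.independent_t(x, x.copy())
        assert r.statistic == pytest.approx(0.0)
        assert r.effect_size == pytest.approx(0.0)

    def test_summary_and_raw_agree_exactly(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1.2, 15)
        raw = st.independent_t(x, y)
        summ = st.independent_t_from_stats(x.mean(), x.std(ddof=1), 12,
                                           y.mean(), y.std(ddof=1), 15)
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.p == pytest.approx(summ.p, abs=1e-12)

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(ValueError, match="pooled"):
            st.independent_t([1.0, 1.0], [1.0, 1.0])

    def test_paired_matches_one_sample_oracle(self):
        from scipy import stats as sps

        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 18), rng.normal(0.3, 1, 18)
        r = st.paired_t(x, y)
        t_ref, p_ref = sps.ttest_1samp(x - y, 0.0)
        assert r.statistic == pytest.approx(t_ref, abs=1e-10)
        assert r.p == pytest.approx(p_ref, abs=1e-10)
        assert r.df == (17.0,)

    def test_paired_constant_difference_raises(self):
        with pytest.raises(ValueError, match="difference variance"):
            st.paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_paired_d_conventions(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 2, 10)
        r = st.paired_t(x, y)
        d = x - y
        assert r.notes["d_dz"] == pytest.approx(d.mean() / d.std(ddof=1))
        assert r.notes["d_dav"] == pytest.approx(
            d.mean() / ((x.std(ddof=1) + y.std(ddof=1)) / 2))


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert st.pearson_r(x, x).statistic == pytest.approx(1.0)
        assert st.pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_covariance_formula_oracle(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r = st.pearson_r(x, y)
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r.statistic == pytest.approx(manual, abs=1e-12)
        assert r.df == (28.0,)


class TestJZSBayesFactor:
    def test_null_centred_t_favours_null(self):
        for n in (3, 18, 50):
            assert st.jzs_bf_ttest(0.0, n, n) < 1.0

    def test_monotone_in_t(self):
        bfs = [st.jzs_bf_ttest(t, 18, 18) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        for t, n1, n2 in ((0.836, 18, 18), (2.5, 12, 15), (1.1, 20, None)):
            mine = st.jzs_bf_ttest(t, n1, n2)
            ref = float(pg.bayesfactor_ttest(t, n1, n2, paired=n2 is None))
            assert mine == pytest.approx(ref, rel=1e-3)

    def test_quadrature_oracle_at_zero(self):
        """At t=0 the marginal ratio reduces to E_g[(1+Ng)^-1/2] under the prior."""
        from scipy import integrate

        n = 18
        N, r = n / 2, np.sqrt(2) / 2
        val, _ = integrate.quad(
            lambda g: (1 + N * g) ** -0.5 * r / np.sqrt(2 * np.pi)
            * g ** -1.5 * np.exp(-r ** 2 / (2 * g)), 0, np.inf, limit=400)
        assert st.jzs_bf_ttest(0.0, n, n) == pytest.approx(val, rel=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.jzs_bf_ttest(np.nan, 18, 18)
        with pytest.raises(ValueError):
            st.jzs_bf_ttest(1.0, 1)


def test_statresult_formatting():
    r = st.StatResult("independent_t", "group", 0.836, (34.0,), 0.409,
                      0.279, "cohen_d", bf10=0.423)
    s = str(r)
    assert "t(34) = 0.836" in s and "d = 0.279" in s and "BF10 = 0.423" in s
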