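import numpy as np
import pandas as pd
import pytest
from scipy import stats

from antnet.inference import (
    chi_square_2x2,
    cellwise_posthoc,
    cohen_d_from_summary,
    cooks_screen,
    describe,
    group_contrast,
    holm_adjust,
    mixed_anova,
    recommended_p,
    variance_ratio,
    welch_t,
)
from conftest import toy_mixed_data


class TestDescribe:
    def test_symmetric_sample_has_zero_skew(self):
        d = describe([-1.0, 0.0, 1.0])
        assert d.skewness == pytest.approx(0.0)
        assert d.sd == pytest.approx(1.0)

    def test_constant_sample_flagged(self):
        d = describe([5.0, 5.0, 5.0])
        assert d.sd == 0.0 and np.isnan(d.skewness) and np.isnan(d.kurtosis)

    def test_large_normal_sample_has_zero_excess_kurtosis(self):
        x = np.random.default_rng(0).normal(size=20_000)
        d = describe(x)
        se_kurt = np.sqrt(24 / x.size)
        assert abs(d.kurtosis) < 3 * se_kurt

    def test_matches_scipy_moment_estimators(self):
        x = np.random.default_rng(1).gamma(2.0, size=500)
        d = describe(x)
        assert d.skewness == pytest.approx(stats.skew(x, bias=True))
        assert d.kurtosis == pytest.approx(stats.kurtosis(x, bias=True))

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            describe([1.0])


class TestVarianceRatio:
    def test_values_and_symmetry(self):
        x = [1.0, 2.0, 3.0]
        y = [2.0, 4.0, 6.0]
        assert variance_ratio(x, x) == pytest.approx(1.0)
        assert variance_ratio(x, y) == pytest.approx(4.0)
        assert variance_ratio(y, x) == variance_ratio(x, y)

    def test_zero_variance_is_infinite(self):
        assert variance_ratio([1.0, 1.0], [1.0, 2.0]) == np.inf


class TestWelch:
    def test_identical_samples(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == pytest.approx(1.0) and r.d == 0.0

    def test_small_sample_hand_value(self):
        r = welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert r.t == pytest.approx(-1.224744871)
        assert r.df == pytest.approx(4.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 30), rng.normal(0.3, 2, 40)
        r = welch_t(x, y)
        sp = stats.ttest_ind(x, y, equal_var=False)
        assert r.t == pytest.approx(sp.statistic)
        assert r.p == pytest.approx(sp.pvalue)
        assert r.df == pytest.approx(sp.df)

    def test_equals_student_t_with_equal_variances_and_ns(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = welch_t(x, y)
        student = stats.ttest_ind(x, y, equal_var=True)
        assert r.t == pytest.approx(student.statistic)

    def test_cohens_d_from_printed_summaries(self):
        # equal SDs: pooled d reduces to mean difference over common SD
        assert cohen_d_from_summary(11.86, 1.25, 54, 11.84, 1.25, 54) == pytest.approx(0.016)

    def test_one_sided_p_is_half_two_sided(self):
        x, y = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        assert welch_t(x, y, tails="one").p == pytest.approx(welch_t(x, y).p / 2)


class TestHolm:
    def test_step_down_pair(self):
        adj = holm_adjust([0.0012, 0.302])
        assert adj == pytest.approx([0.0024, 0.302])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.04]) == pytest.approx([0.04])

    def test_monotone_and_dominated_by_bonferroni(self):
        p = np.random.default_rng(5).uniform(size=12)
        adj = holm_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj <= np.minimum(1.0, len(p) * p) + 1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(6).uniform(size=9)
        _, adj_sm, _, _ = multipletests(p, method="holm")
        assert holm_adjust(p) == pytest.approx(adj_sm)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestChiSquare:
    def test_equal_proportions_give_zero(self):
        r = chi_square_2x2([[22, 32], [22, 32]])
        assert r.chi2 == 0.0 and r.phi == 0.0 and r.p == pytest.approx(1.0)

    def test_perfect_association(self):
        r = chi_square_2x2([[10, 0], [0, 10]])
        assert r.chi2 == pytest.approx(20.0) and r.phi == pytest.approx(1.0)

    def test_transpose_invariance_and_scipy_agreement(self):
        t = [[12, 7], [5, 21]]
        a, b = chi_square_2x2(t), chi_square_2x2(np.transpose(t))
        assert a.chi2 == pytest.approx(b.chi2)
        sp = stats.chi2_contingency(t, correction=False)
        assert a.chi2 == pytest.approx(sp.statistic)
        assert a.p == pytest.approx(sp.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [3, 4]])


# --------------------------------------------------------------------------
# mixed ANOVA


def _rss(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def anova_oracle(df: pd.DataFrame) -> dict:
    """Brute-force SS partition via nested least-squares projections."""
    y = df["composite"].to_numpy(dtype=float)
    subj = pd.get_dummies(df["participant_id"]).to_numpy(dtype=float)
    grp = pd.get_dummies(df["group"]).to_numpy(dtype=float)
    net = pd.get_dummies(df["network"]).to_numpy(dtype=float)
    inter = np.einsum("ij,ik->ijk", grp, net).reshape(len(df), -1)
    ones = np.ones((len(df), 1))

    m0 = _rss(y, ones)
    m1 = _rss(y, np.hstack([ones, grp]))
    m2 = _rss(y, np.hstack([ones, subj]))
    m3 = _rss(y, np.hstack([ones, subj, net]))
    m4 = _rss(y, np.hstack([ones, subj, net, inter]))
    return {
        "total": m0,
        "group": m0 - m1,
        "subject": m1 - m2,
        "network": m2 - m3,
        "interaction": m3 - m4,
        "error": m4,
    }


class TestMixedAnova:
    def test_ss_match_projection_oracle(self):
        df = toy_mixed_data(seed=11, n_per=5)
        res = mixed_anova(df)
        oracle = anova_oracle(df)
        tab = res.table.set_index("effect")
        assert tab.loc["group", "SS"] == pytest.approx(oracle["group"], rel=1e-10)
        assert tab.loc["network", "SS"] == pytest.approx(oracle["network"], rel=1e-10)
        assert tab.loc["group:network", "SS"] == pytest.approx(oracle["interaction"], rel=1e-10)

    def test_ss_conservation(self):
        df = toy_mixed_data(seed=12, n_per=4)
        res = mixed_anova(df)
        oracle = anova_oracle(df)
        parts = res.table["SS"].sum() + oracle["subject"] + oracle["error"]
        assert parts == pytest.approx(oracle["total"], rel=1e-8)

    def test_frozen_r_car_oracle(self):
        # seed-42 toy scored independently with R car::Anova (sum contrasts)
        res = mixed_anova(toy_mixed_data(seed=42, n_per=8))
        tab = res.table.set_index("effect")
        assert tab.loc["group", "SS"] == pytest.approx(1.4874, abs=5e-5)
        assert tab.loc["group", "F"] == pytest.approx(0.4003, abs=5e-5)
        assert tab.loc["network", "SS"] == pytest.approx(29.7303, abs=5e-5)
        assert tab.loc["network", "F"] == pytest.approx(11.0488, abs=5e-5)
        assert tab.loc["network", "p"] == pytest.approx(0.0002903, abs=5e-7)
        assert tab.loc["group:network", "SS"] == pytest.approx(0.4824, abs=5e-5)
        assert res.mauchly.W == pytest.approx(0.24357, abs=5e-6)
        assert res.mauchly.p == pytest.approx(0.00010306, abs=5e-9)
        assert res.gg_epsilon == pytest.approx(0.5693375, abs=5e-8)
        assert tab.loc["network", "p_gg"] == pytest.approx(0.003364048, abs=5e-8)
        assert tab.loc["group:network", "p_gg"] == pytest.approx(0.709910195, abs=5e-8)

    def test_matches_pingouin(self):
        import pingouin as pg

        df = toy_mixed_data(seed=13, n_per=7)
        res = mixed_anova(df).table.set_index("effect")
        pga = pg.mixed_anova(
            data=df, dv="composite", within="network", between="group",
            subject="participant_id",
        ).set_index("Source")
        assert res.loc["group", "F"] == pytest.approx(pga.loc["group", "F"])
        assert res.loc["network", "F"] == pytest.approx(pga.loc["network", "F"])
        assert res.loc["group:network", "F"] == pytest.approx(pga.loc["Interaction", "F"])

    def test_two_level_within_factor_forces_sphericity(self):
        df = toy_mixed_data(seed=14, n_per=6)
        df = df.loc[df["network"] != "orienting"]
        res = mixed_anova(df)
        assert res.gg_epsilon == 1.0
        assert res.mauchly is None
        tab = res.table.set_index("effect")
        assert tab.loc["network", "p_gg"] == pytest.approx(tab.loc["network", "p"])

    def test_gg_correction_is_conservative_for_f_above_one(self):
        # deflating both dfs can only raise the p of an effect with F >= 1
        # (for F < 1 the tail relation inverts; R's car shows the same)
        res = mixed_anova(toy_mixed_data(seed=42, n_per=8))
        tab = res.table.set_index("effect")
        assert res.gg_epsilon < 1
        big = tab.loc[tab["F"] >= 1]
        assert (big["p_gg"] >= big["p"] - 1e-15).all()
        assert tab.loc["network", "F"] >= 1  # the claim is exercised

    def test_ges_bounds_and_below_partial_eta(self):
        df = toy_mixed_data(seed=15, n_per=6)
        res = mixed_anova(df)
        oracle = anova_oracle(df)
        tab = res.table.set_index("effect")
        assert ((tab["ges"] >= 0) & (tab["ges"] <= 1)).all()
        partial = {
            "group": oracle["group"] / (oracle["group"] + oracle["subject"]),
            "network": oracle["network"] / (oracle["network"] + oracle["error"]),
            "group:network": oracle["interaction"] / (oracle["interaction"] + oracle["error"]),
        }
        for eff, pe in partial.items():
            assert tab.loc[eff, "ges"] <= pe + 1e-12

    def test_degenerate_constant_response_flagged(self):
        df = toy_mixed_data(seed=16, n_per=4)
        df["composite"] = 1.0
        res = mixed_anova(df)
        assert res.table["SS"].sum() == pytest.approx(0.0)
        assert res.table["F"].isna().all()

    def test_unbalanced_design_rejected(self):
        df = toy_mixed_data(seed=17, n_per=4).iloc[:-1]
        with pytest.raises(ValueError, match="within levels"):
            mixed_anova(df)

    def test_recommended_p_follows_mauchly(self):
        res = mixed_anova(toy_mixed_data(seed=42, n_per=8))
        tab = res.table.set_index("effect")
        assert res.mauchly.p < 0.05
        assert recommended_p(res, "group:network") == tab.loc["group:network", "p_gg"]


class TestContrasts:
    def test_group_contrast_equals_student_t_on_subject_means(self):
        df = toy_mixed_data(seed=18, n_per=9)
        res = mixed_anova(df)
        c = group_contrast(res)
        means = df.groupby(["participant_id", "group"])["composite"].mean().reset_index()
        a = means.loc[means["group"] == "a", "composite"]
        b = means.loc[means["group"] == "b", "composite"]
        student = stats.ttest_ind(a, b, equal_var=True)
        assert c.t == pytest.approx(student.statistic)
        assert c.df == len(means) - 2
        assert np.sign(c.t) == np.sign(a.mean() - b.mean())

    def test_identical_groups_give_zero_contrast(self):
        df = toy_mixed_data(seed=19, n_per=5)
        wide = df.pivot_table(index=["participant_id", "group"], columns="network", values="composite")
        mirrored = wide.reset_index()
        mirrored["group"] = np.repeat(["a", "b"], len(mirrored) // 2)
        # make group b an exact copy of group a
        vals = mirrored.loc[mirrored["group"] == "a", ["alerting", "executive", "orienting"]].to_numpy()
        mirrored.loc[mirrored["group"] == "b", ["alerting", "executive", "orienting"]] = vals
        long = mirrored.melt(
            id_vars=["participant_id", "group"], var_name="network", value_name="composite"
        )
        long["participant_id"] = long["participant_id"] + long["group"]
        c = group_contrast(mixed_anova(long))
        assert c.t == pytest.approx(0.0, abs=1e-12)

    def test_cellwise_df_within_satterthwaite_bounds(self):
        df = toy_mixed_data(seed=20, n_per=10)
        res = mixed_anova(df)
        contrasts = cellwise_posthoc(res)
        n, g, k = 20, 2, 3
        for c in contrasts:
            assert n - g < c.df < g * k * (n // g - 1) + n - g + 1

    def test_planted_executive_shift_dominates(self):
        rng = np.random.default_rng(21)
        rows = []
        for g, lab in enumerate(["a", "b"]):
            for i in range(12):
                subj = rng.normal(0, 0.3)
                for net in ["alerting", "orienting", "executive"]:
                    shift = 1.5 if (net == "executive" and g == 1) else 0.0
                    rows.append((f"{lab}{i}", lab, net, subj + shift + rng.normal(0, 0.4)))
        df = pd.DataFrame(rows, columns=["participant_id", "group", "network", "composite"])
        contrasts = {c.label.split(":")[0]: c for c in cellwise_posthoc(mixed_anova(df))}
        assert abs(contrasts["executive"].t) > abs(contrasts["alerting"].t)
        assert abs(contrasts["executive"].t) > abs(contrasts["orienting"].t)
        assert contrasts["executive"].p_holm < 0.05


class TestCooks:
    def test_exchangeable_points_all_below_cutoff(self):
        X = np.tile(np.arange(5.0), 4)
        y = 2.0 + 3.0 * X
        y = y + np.tile([0.1, -0.1], 10)
        diag = cooks_screen(y, X)
        assert diag.flagged.size == 0
        assert np.ptp(diag.d.reshape(4, 5), axis=0).max() < 1e-12

    def test_gross_outlier_has_max_distance(self):
        rng = np.random.default_rng(22)
        X = np.linspace(0, 10, 30)
        y = 1.0 + 0.5 * X + rng.normal(0, 0.2, 30)
        y[7] += 8.0
        diag = cooks_screen(y, X)
        assert diag.d.argmax() == 7

    def test_matches_leave_one_out_refit_oracle(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(15, 2))
        y = 1.0 + X @ [2.0, -1.0] + rng.normal(0, 0.5, 15)
        diag = cooks_screen(y, X)
        X1 = np.column_stack([np.ones(15), X])
        beta = np.linalg.lstsq(X1, y, rcond=None)[0]
        s2 = np.sum((y - X1 @ beta) ** 2) / (15 - 3)
        M = X1.T @ X1
        for i in range(15):
            mask = np.arange(15) != i
            beta_i = np.linalg.lstsq(X1[mask], y[mask], rcond=None)[0]
            delta = beta - beta_i
            d_oracle = delta @ M @ delta / (3 * s2)
            assert diag.d[i] == pytest.approx(d_oracle, rel=1e-8)

    def test_cutoff_is_median_f(self):
        diag = cooks_screen(np.arange(108.0) + np.random.default_rng(1).normal(size=108), np.arange(108.0))
        assert diag.cutoff == pytest.approx(stats.f.ppf(0.5, 2, 106))
        assert diag.cutoff == pytest.approx(0.697, abs=5e-3)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError, match="rank"):
            cooks_screen(np.arange(10.0), X)
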