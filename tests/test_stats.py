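"""Inference chain vs independent oracles (GLM projection, enumeration)."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from toolreach import stats
from toolreach.datasets import load_pd_clinical
from toolreach.simulate import session_scores

from oracles import glm_mixed_anova, mann_whitney_exact, spearman_direct


def _long(Y, gidx, age=None):
    N, k = Y.shape
    rows = []
    for i in range(N):
        for j in range(k):
            row = {"participant_id": f"s{i}", "group": "PD" if gidx[i] == 0 else "HC",
                   "session": f"t{j}", "value": Y[i, j]}
            if age is not None:
                row["age"] = age[i]
            rows.append(row)
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_null_data_zero_f(self):
        Y = np.full((8, 2), 3.0)
        gidx = np.array([0] * 4 + [1] * 4)
        res = stats.mixed_anova(_long(Y, gidx))
        assert np.allclose(res.table["F"], 0.0)

    def test_study_shape_dfs(self, rng):
        Y = rng.normal(size=(32, 2))
        gidx = np.array([0] * 14 + [1] * 18)
        res = stats.mixed_anova(_long(Y, gidx))
        assert (res.table["df2"] == 30).all()
        Y3 = rng.normal(size=(31, 3))
        res3 = stats.mixed_anova(_long(Y3, np.array([0] * 13 + [1] * 18)))
        assert res3.table.loc["Time", "df1"] == 2
        assert res3.table.loc["Time", "df2"] == 58
        assert res3.table.loc["Group", "df2"] == 29

    def test_matches_glm_projection_oracle(self, rng):
        """F and p equal an explicit design-matrix decomposition to 1e-8."""
        for _ in range(15):
            n1, n2 = rng.integers(3, 9, size=2)
            k = int(rng.integers(2, 4))
            Y = rng.normal(size=(n1 + n2, k)) + rng.normal(size=(n1 + n2, 1))
            gidx = np.array([0] * n1 + [1] * n2)
            res = stats.mixed_anova(_long(Y, gidx))
            oracle = glm_mixed_anova(Y, gidx)
            for eff in ("Group", "Time", "Group x Time"):
                assert res.table.loc[eff, "F"] == pytest.approx(
                    oracle[eff]["F"], rel=1e-8
                )
                assert res.table.loc[eff, "p"] == pytest.approx(
                    oracle[eff]["p"], rel=1e-8, abs=1e-12
                )

    def test_matches_pingouin_balanced(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(20, 2))
        gidx = np.array([0] * 10 + [1] * 10)
        df = _long(Y, gidx)
        res = stats.mixed_anova(df)
        out = pg.mixed_anova(data=df, dv="value", within="session",
                             between="group", subject="participant_id")
        out = out.set_index("Source")
        assert res.table.loc["Group", "F"] == pytest.approx(out.loc["group", "F"], rel=1e-6)
        assert res.table.loc["Time", "F"] == pytest.approx(out.loc["session", "F"], rel=1e-6)
        assert res.table.loc["Group x Time", "F"] == pytest.approx(
            out.loc["Interaction", "F"], rel=1e-6
        )

    def test_partial_eta_sq_internal_consistency(self, rng):
        Y = rng.normal(size=(12, 2))
        gidx = np.array([0] * 5 + [1] * 7)
        res = stats.mixed_anova(_long(Y, gidx))
        ss_sub = res.ms_subject * res.df_subject
        ss_w = res.ms_within * res.df_within
        for eff, err in [("Group", ss_sub), ("Time", ss_w), ("Group x Time", ss_w)]:
            ss = res.table.loc[eff, "ss"]
            assert res.table.loc[eff, "partial_eta_sq"] == pytest.approx(ss / (ss + err))
            assert 0 <= res.table.loc[eff, "partial_eta_sq"] <= 1

    def test_missing_cell_rejected(self, rng):
        df = _long(rng.normal(size=(6, 2)), np.array([0, 0, 0, 1, 1, 1]))
        df = df.iloc[:-1]  # drop one cell
        with pytest.raises(ValueError, match="missing cells"):
            stats.mixed_anova(df)

    def test_gg_epsilon_bounds(self, rng):
        Y = rng.normal(size=(20, 3))
        Y[:, 2] += 0.8 * Y[:, 1]  # induce unequal covariances
        gidx = np.array([0] * 10 + [1] * 10)
        dec = stats.mixed_anova_arrays(Y, gidx, gg_correction=True)
        assert 0.5 <= dec["epsilon"] <= 1.0
        res_gg = stats.mixed_anova(_long(Y, gidx), gg_correction=True)
        res = stats.mixed_anova(_long(Y, gidx))
        assert res_gg.table.loc["Time", "p"] >= res.table.loc["Time", "p"] - 1e-12

    def test_type_one_error_calibrated(self):
        """Null simulator: each effect rejects at ~5% (300 replicates)."""
        rng = np.random.default_rng(2024)
        rejects = np.zeros(3)
        reps = 300
        for _ in range(reps):
            df = session_scores(10, 12, 2, rng=rng)
            res = stats.mixed_anova(df, dv="value")
            rejects += (res.table["p"].to_numpy() < 0.05)
        rates = rejects / reps
        half = 2.58 * np.sqrt(0.05 * 0.95 / reps)  # 99% binomial band
        assert np.all(rates > 0.05 - half) and np.all(rates < 0.05 + half)


class TestAncova:
    def test_covariate_equal_to_response_kills_group_effect(self, rng):
        gidx = np.array([0] * 8 + [1] * 8)
        base = rng.normal(size=16) + np.where(gidx == 0, 1.0, 0.0)
        Y = np.column_stack([base, base])
        res = stats.ancova_mixed(_long(Y, gidx, age=base), covariate="age")
        assert res.table.loc["Group", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_covariate_adjusted_means_equal_raw(self, rng):
        gidx = np.array([0] * 6 + [1] * 6)
        age = np.tile(np.arange(6), 2).astype(float)  # identical per group
        Y = rng.normal(size=(12, 2))
        res_c = stats.ancova_mixed(_long(Y, gidx, age=age), covariate="age")
        res = stats.mixed_anova(_long(Y, gidx))
        pd.testing.assert_frame_equal(
            res_c.cell_means, res.cell_means, check_exact=False, atol=1e-10
        )

    def test_uncorrelated_covariate_converges_to_anova(self):
        rng = np.random.default_rng(5)
        n = 200
        gidx = np.array([0] * n + [1] * n)
        Y = rng.normal(size=(2 * n, 2)) + rng.normal(size=(2 * n, 1))
        Y[gidx == 0] += 0.3
        age = rng.normal(50, 10, size=2 * n)
        res = stats.mixed_anova(_long(Y, gidx))
        res_c = stats.ancova_mixed(_long(Y, gidx, age=age), covariate="age")
        for eff in ("Group", "Time", "Group x Time"):
            assert res_c.table.loc[eff, "F"] == pytest.approx(
                res.table.loc[eff, "F"], rel=0.05, abs=0.1
            )

    def test_ancova_dfs(self, rng):
        Y = rng.normal(size=(32, 2))
        gidx = np.array([0] * 14 + [1] * 18)
        age = rng.normal(60, 10, 32)
        res = stats.ancova_mixed(_long(Y, gidx, age=age), covariate="age")
        assert res.table.loc["Group", "df2"] == 29
        assert res.table.loc["Time", "df2"] == 29

    def test_constant_covariate_rejected(self, rng):
        Y = rng.normal(size=(8, 2))
        gidx = np.array([0] * 4 + [1] * 4)
        with pytest.raises(ValueError, match="constant"):
            stats.ancova_mixed(_long(Y, gidx, age=np.full(8, 50.0)), covariate="age")


class TestEmm:
    def test_symmetric_null_all_p_one(self):
        # identical subject-offset pattern in both groups, no time change
        offsets = np.tile(np.arange(5) * 0.1, 2)
        Y = 1.0 + np.column_stack([offsets, offsets])
        gidx = np.array([0] * 5 + [1] * 5)
        res = stats.mixed_anova(_long(Y, gidx))
        for c in stats.emm_simple_effects(res):
            assert c.p_adjusted == pytest.approx(1.0)

    def test_bonferroni_monotone(self, rng):
        Y = rng.normal(size=(14, 2))
        gidx = np.array([0] * 7 + [1] * 7)
        res = stats.mixed_anova(_long(Y, gidx))
        for c in stats.emm_simple_effects(res):
            assert c.p_adjusted >= c.p_raw - 1e-15
            assert c.p_adjusted <= 1.0

    def test_detects_controls_only_time_effect(self):
        """Time contrast significant only in the group carrying the effect."""
        rng = np.random.default_rng(77)
        hits = 0
        reps = 60
        for _ in range(reps):
            eff = np.array([[0.0, 0.0], [0.0, 0.8]])
            df = session_scores(30, 30, 2, cell_effects=eff, rng=rng)
            res = stats.mixed_anova(df)
            comps = {c.contrast: c for c in stats.emm_simple_effects(res)}
            time_pd = comps["s1 - s0 | PD"]
            time_hc = comps["s1 - s0 | control"]
            if time_hc.p_adjusted < 0.05 and time_pd.p_adjusted >= 0.05:
                hits += 1
        assert hits / reps >= 0.85


class TestRankStats:
    def test_spearman_identity_reversal(self, rng):
        x = rng.normal(size=10)
        assert stats.spearman_rho(x, x).rho == pytest.approx(1.0)
        assert stats.spearman_rho(x, -x).rho == pytest.approx(-1.0)

    def test_spearman_matches_direct_formula(self, rng):
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            assert stats.spearman_rho(x, y).rho == pytest.approx(
                spearman_direct(x, y), abs=1e-12
            )

    def test_spearman_constant_rejected(self):
        with pytest.raises(ValueError):
            stats.spearman_rho([1, 1, 1], [1, 2, 3])

    def test_mwu_separation_and_symmetry(self):
        r = stats.mann_whitney_u([1, 2], [3, 4])
        assert r.U == 0
        a = [1.0, 2.0, 3.0]
        r2 = stats.mann_whitney_u(a, a)
        assert r2.U == pytest.approx(len(a) ** 2 / 2)
        assert r2.p == pytest.approx(1.0)

    def test_mwu_exact_matches_enumeration_oracle(self, rng):
        for _ in range(8):
            n1, n2 = rng.integers(3, 8, size=2)
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            u, p = mann_whitney_exact(a, b)
            r = stats.mann_whitney_u(a, b)
            assert r.method == "exact"
            assert r.U == pytest.approx(min(u, n1 * n2 - u))
            assert r.p == pytest.approx(p, abs=1e-12)
        # with ties
        a = np.array([1.0, 2.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0])
        u, p = mann_whitney_exact(a, b)
        r = stats.mann_whitney_u(a, b)
        assert r.p == pytest.approx(p, abs=1e-12)

    def test_mwu_exact_matches_scipy_no_ties(self, rng):
        a = rng.normal(size=7)
        b = rng.normal(size=7)
        r = stats.mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert r.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_mwu_normal_approximation_large_n(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(0.2, 1.0, size=35)
        r = stats.mann_whitney_u(a, b)
        assert r.method == "normal"
        ref = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=False,
                               alternative="two-sided")
        assert r.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestDescribe:
    def test_clinical_table_footer(self):
        """Printed per-patient values reproduce the printed mean (SD) row."""
        tab = load_pd_clinical()
        assert stats.describe(tab.updrs, "truncate") == (30, 13)
        assert stats.describe(tab.duration, "truncate") == (7, 3)
        assert stats.describe(tab.age, "truncate") == (66, 8)
        assert stats.describe(tab.education, "truncate") == (9, 3)

    def test_round_vs_truncate(self):
        vals = [1.6, 1.6, 1.6]
        vals2 = [1.6, 1.6, 1.9]
        assert stats.describe(vals2, "round")[0] == 2
        assert stats.describe(vals2, "truncate")[0] == 1

    def test_constant_sd_zero(self):
        assert stats.describe([5, 5, 5], "round")[1] == 0


class TestPower:
    def test_null_effect_equals_alpha(self):
        assert stats.power_two_sample(0.0, 14, 14, 0.05) == pytest.approx(0.05, abs=1e-9)

    def test_large_effect_saturates(self):
        assert stats.power_two_sample(10.0, 14, 14) > 0.999999

    def test_monotone_in_d_n_alpha(self):
        base = stats.power_two_sample(0.5, 14, 14, 0.05)
        assert stats.power_two_sample(0.8, 14, 14, 0.05) > base
        assert stats.power_two_sample(0.5, 30, 30, 0.05) > base
        assert stats.power_two_sample(0.5, 14, 14, 0.10) > base

    def test_matches_quadrature_oracle(self):
        """Noncentral-t power vs direct numeric integration of the density."""
        d, n1, n2, alpha = 0.5, 14, 14, 0.05
        df = n1 + n2 - 2
        ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
        tc = sps.t.ppf(1 - alpha / 2, df)
        upper, _ = integrate.quad(lambda x: sps.nct.pdf(x, df, ncp), tc, np.inf)
        lower, _ = integrate.quad(lambda x: sps.nct.pdf(x, df, ncp), -np.inf, -tc)
        assert stats.power_two_sample(d, n1, n2, alpha) == pytest.approx(
            upper + lower, abs=1e-4
        )
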