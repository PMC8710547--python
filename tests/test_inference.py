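"""Covariate-adjusted inference, multiple-testing control, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import funconn as fc
from funconn.cohort import GROUPS
from funconn.inference import correlation_table, nodal_ancova_table

from oracles import bh_stepup_oracle


def make_meta(rng, n_per_group=(12, 10, 10)):
    rows = []
    for grp, n in zip(GROUPS, n_per_group):
        for _ in range(n):
            rows.append(dict(
                subject_id=f"s{len(rows):03d}", group=grp,
                age=float(rng.normal(52, 9)),
                sex="male" if rng.random() < 0.6 else "female",
                education=float(rng.normal(10, 3)),
                sds_score=float(rng.normal(38, 6)),
            ))
    return pd.DataFrame(rows)


class TestAncova:
    def test_matches_statsmodels(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        meta = make_meta(rng)
        y = rng.normal(0.18, 0.01, len(meta))
        y[meta["group"] == "MHD_CI"] -= 0.008
        res = fc.ancova_auc(y, meta)
        df = meta.assign(y=y, sex_i=(meta["sex"] == "male").astype(float))
        fit = smf.ols("y ~ C(group, Treatment('HC')) + age + sex_i + education + sds_score",
                      data=df).fit()
        tab = anova_lm(fit, typ=2)
        row = [i for i in tab.index if "group" in i][0]
        assert res.f_stat == pytest.approx(tab.loc[row, "F"], rel=1e-8)
        assert res.p_omnibus == pytest.approx(tab.loc[row, "PR(>F)"], rel=1e-8)
        tt = fit.t_test("C(group, Treatment('HC'))[T.MHD_CI] - "
                        "C(group, Treatment('HC'))[T.MHD_noCI] = 0")
        expected = min(float(tt.pvalue) * 3.0, 1.0)
        assert res.posthoc_p["CI_vs_noCI"] == pytest.approx(expected, rel=1e-8)

    def test_constant_covariates_reduce_to_anova(self, rng):
        meta = make_meta(rng)
        for c in ("age", "education", "sds_score"):
            meta[c] = 5.0
        meta["sex"] = "male"
        y = rng.normal(0, 1, len(meta))
        with pytest.warns(UserWarning, match="collinear"):
            res = fc.ancova_auc(y, meta)
        groups = [y[(meta["group"] == g).to_numpy()] for g in GROUPS]
        f, p = stats.f_oneway(*groups)
        assert res.p_omnibus == pytest.approx(p, rel=1e-10)

    def test_confound_mediated_effect_vanishes_after_adjustment(self, rng):
        meta = make_meta(rng, (20, 20, 20))
        # group effect entirely carried by SDS
        meta["sds_score"] = 30.0 + 6.0 * (meta["group"] == "MHD_CI") + rng.normal(0, 0.5, 60)
        y = 0.01 * meta["sds_score"].to_numpy() + rng.normal(0, 0.005, 60)
        adjusted = fc.ancova_auc(y, meta)
        unadjusted = fc.ancova_auc(y, meta, covariates=("age",))
        assert unadjusted.p_omnibus < 0.01
        assert adjusted.p_omnibus > 0.05

    def test_small_group_errors(self, rng):
        meta = make_meta(rng, (2, 2, 2)).drop(index=[5])
        y = rng.normal(0, 1, len(meta))
        with pytest.raises(ValueError, match=">= 2"):
            fc.ancova_auc(y, meta.reset_index(drop=True))

    def test_missing_rows_dropped_with_warning(self, rng):
        meta = make_meta(rng)
        meta.loc[3, "age"] = np.nan
        y = rng.normal(0, 1, len(meta))
        with pytest.warns(UserWarning, match="missing"):
            res = fc.ancova_auc(y, meta)
        assert res.n_used == len(meta) - 1


class TestBonferroni:
    def test_cap_multiply_zero(self):
        assert fc.bonferroni_posthoc([0.4, 0.01, 0.0]) == pytest.approx([1.0, 0.03, 0.0])

    def test_never_below_input(self, rng):
        p = rng.random(3)
        assert np.all(fc.bonferroni_posthoc(p) >= p)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            fc.bonferroni_posthoc([0.1, 1.5, 0.2])


class TestBhFdr:
    def test_hand_example(self):
        q = fc.bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]))
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.5], abs=1e-12)

    def test_single_and_equal(self):
        assert fc.bh_fdr(np.array([0.07]))[0] == pytest.approx(0.07)
        assert fc.bh_fdr(np.full(5, 0.2)) == pytest.approx(np.full(5, 0.2))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 40))
    def test_matches_stepup_oracle_and_order_invariance(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.random(m)
        q = fc.bh_fdr(p)
        assert np.allclose(q, bh_stepup_oracle(p), atol=1e-12)
        perm = rng.permutation(m)
        assert np.allclose(fc.bh_fdr(p[perm]), q[perm], atol=1e-12)

    def test_empty(self):
        assert fc.bh_fdr(np.array([])).size == 0


class TestPartialSpearman:
    def test_no_covariates_equals_spearman(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        res = fc.partial_spearman(x, y)
        rho, p = stats.spearmanr(x, y)
        assert res.r == pytest.approx(rho, abs=1e-10)

    def test_monotone_transform_r_one(self, rng):
        x = rng.normal(size=40)
        res = fc.partial_spearman(x, np.exp(x))
        assert res.r == pytest.approx(1.0)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        x = rng.normal(size=50)
        z = rng.normal(size=50)
        y = x + z + rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        res = fc.partial_spearman(x, y, z[:, None])
        ref = pg.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)

    def test_recovers_generating_partial_correlation(self, rng):
        """y = x + z + e: the x-y partial correlation given z is
        1/sqrt(2) on the Pearson scale (~0.69 after rank transform)."""
        target = 6.0 / np.pi * np.arcsin(1.0 / (2.0 * np.sqrt(2.0)))
        rs = []
        for _ in range(400):
            x = rng.normal(size=120)
            z = rng.normal(size=120)
            y = x + z + rng.normal(size=120)
            rs.append(fc.partial_spearman(x, y, z[:, None]).r)
        assert np.mean(rs) == pytest.approx(target, abs=0.05)

    def test_zero_variance_errors(self, rng):
        with pytest.raises(ValueError, match="variance"):
            fc.partial_spearman(np.ones(20), rng.normal(size=20))


class TestCohortTable:
    def test_identical_groups_give_p_one(self):
        base = dict(age=[50, 55, 60, 65], education=[8, 10, 12, 14],
                    moca=[24, 26, 27, 28], sds_score=[30, 35, 40, 45])
        rows = []
        for grp in GROUPS:
            for i in range(4):
                rows.append(dict(
                    subject_id=f"{grp}{i}", group=grp, sex="male" if i % 2 else "female",
                    **{k: v[i] for k, v in base.items()},
                ))
        meta = pd.DataFrame(rows)
        with pytest.warns(UserWarning):
            table = fc.cohort_table(meta)
        assert (table.set_index("variable")["p"] > 0.99).all()

    def test_patient_only_variable_two_group_test(self, small_cohort):
        table = fc.cohort_table(small_cohort.meta)
        row = table[table["variable"] == "dialysis_months"].iloc[0]
        assert row["HC"] == "-"
        assert row["test"] == "mann-whitney"
        assert 0 <= row["p"] <= 1

    def test_chi_square_matches_hand_computation(self):
        rows = []
        males = {"HC": 8, "MHD_noCI": 9, "MHD_CI": 3}
        females = {"HC": 4, "MHD_noCI": 1, "MHD_CI": 7}
        for grp in GROUPS:
            for _ in range(males[grp]):
                rows.append(dict(subject_id=f"m{len(rows)}", group=grp, sex="male"))
            for _ in range(females[grp]):
                rows.append(dict(subject_id=f"f{len(rows)}", group=grp, sex="female"))
        meta = pd.DataFrame(rows)
        meta["age"] = np.arange(len(meta), dtype=float)  # keep other rows happy
        with pytest.warns(UserWarning):
            table = fc.cohort_table(meta)
        p_pkg = table[table["variable"] == "sex (male/female)"]["p"].iloc[0]
        obs = np.array([[8, 9, 3], [4, 1, 7]], dtype=float)
        row_tot = obs.sum(1, keepdims=True)
        col_tot = obs.sum(0, keepdims=True)
        exp = row_tot @ col_tot / obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert p_pkg == pytest.approx(float(stats.chi2.sf(chi2, 2)), abs=1e-10)


class TestTables:
    def test_nodal_fdr_table_structure(self, rng):
        meta = make_meta(rng)
        auc = pd.DataFrame(rng.normal(0.2, 0.02, size=(len(meta), 12)))
        table = nodal_ancova_table(auc, meta, metric="NCp")
        assert len(table) == 12
        assert set(["p", "q", "significant", "p1", "p2", "p3"]) <= set(table.columns)
        assert (table["q"] >= table["p"] - 1e-12).all()

    def test_correlation_table_blockwise_fdr(self, rng):
        n = 30
        params = pd.DataFrame({"Cp": rng.normal(size=n), "Eloc": rng.normal(size=n)})
        cog = pd.DataFrame({"moca": rng.normal(size=n), "dst_t": rng.normal(size=n)})
        covs = pd.DataFrame({"age": rng.normal(size=n)})
        table = correlation_table(params, cog, covs)
        assert len(table) == 4
        for (_, score), sub in table.groupby(["block", "score"]):
            assert np.allclose(fc.bh_fdr(sub["p"].to_numpy()), sub["q"].to_numpy())
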