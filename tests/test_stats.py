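"""Mixed-design RM-ANCOVA, Greenhouse–Geisser, BH-FDR and post-hoc grids.

The ANCOVA is validated two ways: against frozen reference values from an
independent repeated-measures implementation (R car::Anova, Type III with
sum-to-zero coding, run on the two deterministic toy datasets
regenerated below), and at run time against a statsmodels OLS ANOVA of
the between-subject stratum.
"""

import numpy as np
import pandas as pd
import pytest

from eegmse.montage import MONTAGE_1020
from eegmse.mse import ScaleBinProfile
from eegmse.spectral import FREQ_GRID, PSDMatrix
from eegmse.stats import (
    bh_fdr,
    fit_rm_ancova,
    greenhouse_geisser_epsilon,
    posthoc_ttests,
    psd_pointwise_tests,
)

from conftest import bh_bruteforce


# ---------------------------------------------------------------------------
# deterministic toy datasets (regenerated, not stored)
# ---------------------------------------------------------------------------

def toy_2x2():
    rng = np.random.default_rng(42)
    n = 8
    groups = ["high"] * 4 + ["low"] * 4
    sex = ["M", "F", "M", "F", "F", "M", "F", "M"]
    age = np.round(rng.uniform(65, 85, n), 1)
    base = np.array([2.0, 2.1, 1.9, 2.05])
    g_eff = np.array([0.15, 0.05, 0.10, 0.20])
    Y = (base + np.where(np.array(groups) == "high", 1, 0)[:, None] * g_eff
         + 0.01 * (age[:, None] - 75) + rng.normal(0, 0.08, (n, 4)))
    return _long(np.round(Y, 6), groups, age, sex, ne=2, nb=2)


def toy_3x2():
    rng = np.random.default_rng(7)
    n = 10
    groups = ["high"] * 5 + ["low"] * 5
    sex = ["M", "F", "M", "F", "M", "F", "M", "F", "F", "M"]
    age = np.round(rng.uniform(65, 85, n), 1)
    base = np.array([2.0, 2.1, 1.9, 2.05, 2.2, 1.95])
    g_eff = np.array([0.12, 0.05, 0.10, 0.18, 0.02, 0.08])
    L = np.array([[1, 0, 0], [0.8, 0.6, 0], [0.3, 0.2, 0.9]])
    subj_noise = rng.normal(0, 0.1, (n, 3)) @ L.T
    noise = (np.repeat(subj_noise, 2, axis=1) * np.array([1, 0.7] * 3)
             + rng.normal(0, 0.05, (n, 6)))
    Y = np.round(
        base + np.where(np.array(groups) == "high", 1, 0)[:, None] * g_eff
        + 0.008 * (age[:, None] - 75) + noise, 6)
    return _long(Y, groups, age, sex, ne=3, nb=2)


def _long(Y, groups, age, sex, ne, nb):
    rows = []
    for i in range(Y.shape[0]):
        for e in range(ne):
            for b in range(nb):
                rows.append(
                    dict(subject=f"s{i}", group=groups[i], age=age[i],
                         sex=sex[i], electrode=f"e{e + 1}",
                         scale_bin=b + 1, value=Y[i, e * nb + b])
                )
    return pd.DataFrame(rows)


# frozen reference: R car::Anova(mlm, idata, type=3), univariate table
R_ORACLE_2x2 = {
    "Group": (44.82385, 1, 4, 0.0025891),
    "Group x scale": (0.84575, 1, 4, 0.4097986),
    "Group x node": (0.26872, 1, 4, 0.6315487),
    "Node x scale x group": (1.80066, 1, 4, 0.2507422),
}
R_ORACLE_3x2 = {
    "Group": (1.09359, 1, 6, 0.335966, 1.0, 0.335966),
    "Group x scale": (0.63246, 1, 6, 0.456754, 1.0, 0.456754),
    "Group x node": (3.67086, 2, 12, 0.057032, 0.9323938469, 0.06180034791),
    "Node x scale x group": (3.27576, 2, 12, 0.073250, 0.7706390073, 0.09197110639),
}


class TestRmAncova:
    def test_matches_independent_reference_2x2(self):
        out = pd.DataFrame(fit_rm_ancova(toy_2x2())).set_index("effect")
        for eff, (F, df1, df2, p) in R_ORACLE_2x2.items():
            row = out.loc[eff]
            # reference values are printed to 5 significant digits
            assert row["F"] == pytest.approx(F, rel=5e-5)
            assert (row["df1"], row["df2"]) == (df1, df2)
            assert row["p"] == pytest.approx(p, rel=1e-4)

    def test_matches_independent_reference_3x2_with_gg(self):
        out = pd.DataFrame(fit_rm_ancova(toy_3x2())).set_index("effect")
        for eff, (F, df1, df2, p, eps, p_gg) in R_ORACLE_3x2.items():
            row = out.loc[eff]
            assert row["F"] == pytest.approx(F, rel=1e-5)
            assert (row["df1"], row["df2"]) == (df1, df2)
            assert row["p"] == pytest.approx(p, rel=1e-4)
            assert row["gg_epsilon"] == pytest.approx(eps, rel=1e-6)
            assert row["p_gg"] == pytest.approx(p_gg, rel=1e-4)

    def test_partial_eta2_consistent_with_f_ratio(self):
        out = pd.DataFrame(fit_rm_ancova(toy_3x2()))
        for _, r in out.iterrows():
            recon = (r["F"] * r["df1"]) / (r["F"] * r["df1"] + r["df2"])
            assert r["partial_eta2"] == pytest.approx(recon, rel=1e-10)

    def test_between_stratum_agrees_with_statsmodels_ols(self):
        """Dual route: the Group F equals a statsmodels Type-III ANOVA of
        the subject cell-means on group + centred covariates."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        tbl = toy_3x2()
        means = tbl.groupby("subject").agg(
            value=("value", "mean"), group=("group", "first"),
            age=("age", "first"), sex=("sex", "first"),
        ).reset_index()
        means["age_c"] = means["age"] - means["age"].mean()
        means["sex_c"] = (means["sex"] == "M").astype(float)
        means["sex_c"] -= means["sex_c"].mean()
        fit = smf.ols("value ~ C(group, Sum) + age_c + sex_c", data=means).fit()
        F_sm = sm.stats.anova_lm(fit, typ=3).loc["C(group, Sum)", "F"]
        F_mine = pd.DataFrame(fit_rm_ancova(tbl)).set_index("effect").loc["Group", "F"]
        assert F_mine == pytest.approx(F_sm, rel=1e-8)

    def test_gg_p_never_below_unadjusted_p(self):
        out = pd.DataFrame(fit_rm_ancova(toy_3x2()))
        assert np.all(out["p_gg"] >= out["p"] - 1e-12)
        assert np.all((out["gg_epsilon"] > 0) & (out["gg_epsilon"] <= 1))

    def test_listwise_deletion_warns_and_drops(self):
        tbl = toy_3x2()
        tbl.loc[(tbl["subject"] == "s0") & (tbl["electrode"] == "e1")
                & (tbl["scale_bin"] == 1), "value"] = np.nan
        with pytest.warns(UserWarning, match="listwise"):
            out = pd.DataFrame(fit_rm_ancova(tbl))
        assert out["n_subjects"].iloc[0] == 9

    def test_singular_design_raises_informatively(self):
        tbl = toy_2x2()
        tbl["sex"] = "F"
        with pytest.raises(ValueError, match="sex"):
            fit_rm_ancova(tbl)

    def test_covariate_free_model_uses_more_error_df(self):
        out = pd.DataFrame(fit_rm_ancova(toy_2x2(), covariates=()))
        assert out.set_index("effect").loc["Group", "df2"] == 6  # n - 2


class TestGreenhouseGeisser:
    def test_compound_symmetry_gives_one(self):
        k = 5
        W = 0.3 * np.eye(k) + 0.5 * np.ones((k, k))
        assert greenhouse_geisser_epsilon(W) == pytest.approx(1.0)

    def test_rank_one_covariance_hits_lower_bound(self):
        v = np.array([1.0, -0.5, 2.0, 0.3])
        W = np.outer(v, v)
        assert greenhouse_geisser_epsilon(W) == pytest.approx(1 / 3, abs=1e-10)

    def test_matches_textbook_formula_on_random_matrix(self, rng):
        """Box's epsilon via the classical mean-based formula, computed
        independently of the contrast-eigenvalue route."""
        A = rng.standard_normal((4, 4))
        S = A @ A.T
        k = 4
        sbar = S.mean()
        sdiag = np.trace(S) / k
        srow = S.mean(axis=1)
        num = k * k * (sdiag - sbar) ** 2
        den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(srow**2) + k * k * sbar**2)
        assert greenhouse_geisser_epsilon(S) == pytest.approx(num / den, abs=1e-10)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            greenhouse_geisser_epsilon(np.ones((2, 3)))
        with pytest.raises(ValueError):
            greenhouse_geisser_epsilon(np.array([[1.0]]))


class TestBhFdr:
    def test_stepup_examples(self):
        mask, crit = bh_fdr([0.001, 0.02, 0.03, 0.04], 0.05)
        assert mask.all() and crit == 0.04
        mask, crit = bh_fdr([0.5] * 152, 0.05)
        assert not mask.any() and crit == 0.0
        mask, crit = bh_fdr([0.01], 0.05)
        assert mask.all() and crit == 0.01

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(100):
            p = np.round(rng.uniform(0, 1, 8), 2)  # rounding creates ties
            m1, c1 = bh_fdr(p, 0.05)
            m2, c2 = bh_bruteforce(p, 0.05)
            np.testing.assert_array_equal(m1, m2)
            assert c1 == pytest.approx(c2)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 152) ** 2
        mask, _ = bh_fdr(p, 0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(mask, ref)

    def test_order_invariance_and_mask_consistency(self, rng):
        p = rng.uniform(0, 1, 50) ** 3
        perm = rng.permutation(50)
        m1, c1 = bh_fdr(p, 0.05)
        m2, c2 = bh_fdr(p[perm], 0.05)
        np.testing.assert_array_equal(m1[perm], m2)
        assert c1 == c2
        assert np.all(p[m1] <= c1)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], 0.05)


def _binned(values, subjects):
    return ScaleBinProfile(
        values=values, subjects=subjects, labels=list(MONTAGE_1020),
        bin_scale_ranges=[(5 * k + 1, 5 * k + 5) for k in range(8)],
        bin_ms_ranges=[((5 * k + 1) * 5.0, (5 * k + 5) * 5.0) for k in range(8)],
    )


class TestPosthoc:
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_identical_groups_give_t0_p1(self):
        base = np.tile(np.linspace(1.8, 2.2, 8), (19, 1))
        vals = np.tile(base, (8, 1, 1))
        subjects = [f"h{i}" for i in range(4)] + [f"l{i}" for i in range(4)]
        groups = pd.DataFrame(
            {"subject": subjects, "group": ["high"] * 4 + ["low"] * 4}
        )
        grid = posthoc_ttests(_binned(vals, subjects), groups)
        assert grid.t.shape == (19, 8) and grid.n_tests == 152
        np.testing.assert_allclose(grid.t, 0.0)
        np.testing.assert_allclose(grid.p, 1.0)
        assert not grid.q_mask.any() and grid.critical_p == 0.0

    def test_sign_convention_high_minus_low(self, rng):
        vals = rng.normal(2.0, 0.01, (10, 19, 8))
        vals[:5, 3, :] += 1.0  # first five subjects are the high group
        subjects = [f"s{i}" for i in range(10)]
        groups = pd.DataFrame(
            {"subject": subjects, "group": ["high"] * 5 + ["low"] * 5}
        )
        grid = posthoc_ttests(_binned(vals, subjects), groups)
        assert np.all(grid.t[3] > 0)
        assert grid.q_mask[3].all()
        assert np.all(grid.p[grid.q_mask] <= grid.critical_p)

    def test_psd_grid_has_1121_tests(self, rng):
        vals = rng.normal(-10, 1, (8, 19, 59))
        subjects = [f"s{i}" for i in range(8)]
        groups = pd.DataFrame(
            {"subject": subjects, "group": ["high"] * 4 + ["low"] * 4}
        )
        psd = PSDMatrix(vals, subjects, list(MONTAGE_1020), FREQ_GRID.copy())
        grid = psd_pointwise_tests(psd, groups)
        assert grid.n_tests == 1121
        assert grid.t.shape == (19, 59)
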