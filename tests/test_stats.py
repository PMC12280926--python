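"""Regression layer, importance, grouping, ANOVA and Abouheif's test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hoverstab import stats
from hoverstab.reference import MO2NET_COEFFS, PREDICTORS
from hoverstab.synthetic import SyntheticPlan, gen_species_table


class TestOLS:
    def test_exact_line(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        fit = stats.ols(X, [1.0, 3.0, 5.0])
        assert fit.coeffs["intercept"] == pytest.approx(1.0)
        assert fit.coeffs["x"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_table_coefficients_recovered_to_machine_precision(
        self, noiseless_plan
    ):
        t = gen_species_table(noiseless_plan)
        fit = stats.ols(t[list(PREDICTORS)], t["mo2net"])
        for name in ("intercept",) + PREDICTORS:
            assert fit.coeffs[name] == pytest.approx(
                MO2NET_COEFFS[name], rel=1e-9, abs=1e-7
            )
        assert fit.coeffs["fineness_depth"] == pytest.approx(201.28)

    def test_matches_normal_equations_oracle(self):
        """Random small designs agree with the pseudo-inverse solution."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            n, p = 12, 4
            X = pd.DataFrame(
                rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)]
            )
            y = rng.normal(size=n)
            fit = stats.ols(X, y)
            M = np.column_stack([np.ones(n), X.to_numpy()])
            beta = np.linalg.pinv(M) @ y
            np.testing.assert_allclose(fit.coeffs.to_numpy(), beta, atol=1e-8)

    def test_idempotent_on_fitted_values(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        y = rng.normal(size=10)
        fit = stats.ols(X, y)
        refit = stats.ols(X, fit.fitted)
        np.testing.assert_allclose(
            refit.coeffs.to_numpy(), fit.coeffs.to_numpy(), atol=1e-10
        )
        assert refit.r2 == pytest.approx(1.0)

    def test_residuals_plus_fitted_reconstruct_response(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(9, 2)), columns=["a", "b"])
        y = rng.normal(size=9)
        fit = stats.ols(X, y)
        np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-12)

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="rank-deficient.*[ab]"):
            stats.ols(X, [1.0, 2, 3, 4])

    def test_reduced_model_r2_degrades_but_stays_high(self):
        """Dropping one fineness ratio from the calibrated-noise design
        lowers R^2 without destroying predictive power (median over
        replicates)."""
        full_r2, red_r2 = [], []
        for rep in range(30):
            t = gen_species_table(SyntheticPlan(seed=rep, n_species=13))
            full = stats.ols(t[list(PREDICTORS)], t["mo2net"])
            reduced = stats.ols(
                t[[p for p in PREDICTORS if p != "fineness_width"]], t["mo2net"]
            )
            full_r2.append(full.r2)
            red_r2.append(reduced.r2)
        assert np.median(red_r2) < np.median(full_r2)
        assert np.median(red_r2) > 0.4


class TestImportance:
    @staticmethod
    def _design():
        rng = np.random.default_rng(8)
        X = pd.DataFrame(
            {"x1": rng.normal(size=40), "x2": rng.normal(size=40)}
        )
        y = 3.0 * X["x1"].to_numpy()
        return X, y

    def test_irrelevant_variable_has_zero_drop(self):
        X, y = self._design()
        imp = stats.importance(X, y, method="drop")
        assert imp.loc["x2", "delta_r2"] == pytest.approx(0.0, abs=1e-10)

    def test_nested_r2_identity(self):
        X, y = self._design()
        imp = stats.importance(X, y, method="drop")
        without_x1 = stats.ols(X[["x2"]], y)
        full = stats.ols(X, y)
        assert imp.loc["x1", "delta_r2"] == pytest.approx(
            full.r2 - without_x1.r2, abs=1e-12
        )

    def test_drop_and_permute_rankings_agree(self):
        """Well-separated effect sizes give the same importance order
        under both methods."""
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
        y = 5.0 * X["a"] + 1.0 * X["b"] + 0.1 * X["c"] + rng.normal(0, 0.1, 60)
        drop = stats.importance(X, y, method="drop")["delta_r2"]
        perm = stats.importance(X, y, method="permute", n_perm=99, seed=0)[
            "delta_r2"
        ]
        assert list(drop.sort_values(ascending=False).index) == list(
            perm.sort_values(ascending=False).index
        )

    def test_permute_is_seed_reproducible(self):
        X, y = self._design()
        a = stats.importance(X, y, method="permute", n_perm=50, seed=4)
        b = stats.importance(X, y, method="permute", n_perm=50, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_permutations_rejected(self):
        X, y = self._design()
        with pytest.raises(ValueError):
            stats.importance(X, y, method="permute", n_perm=0)


class TestGroups:
    def test_single_outlier_forms_high_group(self):
        net = pd.Series([1.0, 2.0, 3.0, 10.0], index=list("abcd"))
        ratio = pd.Series([2.0, 2.0, 2.0, 2.0], index=list("abcd"))
        labels, means = stats.assign_groups(net, ratio)
        assert list(labels) == ["G1", "G1", "G1", "G2"]
        assert means["mean_mo2net"] == pytest.approx(4.0)

    def test_high_on_ratio_alone_is_enough(self):
        net = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        ratio = pd.Series([1.0, 1.0, 3.0], index=list("abc"))
        labels, _ = stats.assign_groups(net, ratio)
        assert labels["c"] == "G2"

    def test_exactly_at_mean_stays_low(self):
        net = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        ratio = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        labels, _ = stats.assign_groups(net, ratio)
        assert labels["b"] == "G1"  # 2.0 equals the mean: strict 'above'

    def test_identical_values_warn(self):
        net = pd.Series([2.0, 2.0], index=list("ab"))
        with pytest.warns(UserWarning, match="above average"):
            labels, _ = stats.assign_groups(net, net)
        assert set(labels) == {"G1"}


class TestSpeciesComparisons:
    def test_identical_groups_give_f_zero(self):
        F, p = stats.anova_oneway({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_within_variance_flagged(self):
        with pytest.warns(UserWarning, match="infinite"):
            F, p = stats.anova_oneway({"a": [0, 0, 0], "b": [1, 1, 1]})
        assert np.isinf(F) and p == 0.0

    def test_matches_sum_of_squares_oracle(self):
        """Random 3-group designs match a from-scratch SS decomposition
        and scipy's reference implementation to 1e-10."""
        from scipy.stats import f_oneway

        rng = np.random.default_rng(17)
        for _ in range(20):
            groups = {
                k: rng.normal(loc=i, size=rng.integers(3, 8))
                for i, k in enumerate("abc")
            }
            F, p = stats.anova_oneway(groups)
            ref = f_oneway(*groups.values())
            assert F == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_tukey_agrees_with_scipy(self):
        from scipy.stats import tukey_hsd as scipy_tukey

        rng = np.random.default_rng(23)
        groups = {k: rng.normal(loc=i, size=6) for i, k in enumerate("abc")}
        ours = stats.tukey_hsd(groups)
        ref = scipy_tukey(*groups.values())
        for _, row in ours.iterrows():
            i = "abc".index(row["group1"])
            j = "abc".index(row["group2"])
            assert row["p"] == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_species_tests_excludes_singletons(self):
        df = pd.DataFrame(
            {
                "species": ["a"] * 4 + ["b"] * 4 + ["c"],
                "condition": ["hover", "rest"] * 4 + ["hover"],
                "mo2": [200.0, 100, 210, 105, 300, 120, 310, 125, 400],
            }
        )
        with pytest.warns(UserWarning, match="one replicate"):
            out = stats.species_tests(df)
        assert "anova" in out and "hover_vs_rest" in out


class TestAbouheif:
    TREE = "((A,B),(C,D));"
    TRAIT = pd.Series([1.0, 1.0, -1.0, -1.0], index=list("ABCD"))

    def test_proximity_matrix_structure(self):
        W = stats.abouheif_proximity(self.TREE)
        # cherry partner at 1/2, opposite cherry tips at 1/8, rows sum to 1
        raw_row = np.array([0.0, 1 / 2, 1 / 8, 1 / 8])
        np.testing.assert_allclose(W.loc["A"].to_numpy(), raw_row / raw_row.sum())
        np.testing.assert_allclose(W.to_numpy().sum(axis=1), 1.0)
        np.testing.assert_allclose(np.diag(W.to_numpy()), 0.0)

    def test_worked_example_exhaustive(self):
        """Cherry-aligned trait on a balanced 4-taxon tree: C = 1/3 and
        the exhaustive permutation p equals 1/3."""
        res = stats.abouheif(self.TREE, self.TRAIT, method="exhaustive")
        assert res.c_stat == pytest.approx(1 / 3)
        assert res.p == pytest.approx(1 / 3)

    def test_exhaustive_matches_independent_enumeration(self):
        """The permutation distribution agrees with a from-scratch Moran's
        I enumeration over all 4! tip arrangements."""
        W = stats.abouheif_proximity(self.TREE).to_numpy()
        x = self.TRAIT.to_numpy()

        def moran(v):
            vc = v - v.mean()
            return (vc @ W @ vc) / (vc @ vc)

        c_obs = moran(x)
        cs = [moran(np.array(p)) for p in itertools.permutations(x)]
        p_oracle = np.mean([c >= c_obs - 1e-12 for c in cs])
        res = stats.abouheif(self.TREE, self.TRAIT, method="exhaustive")
        assert res.p == pytest.approx(p_oracle)

    def test_relabeling_invariance(self):
        tree2 = "((C,D),(A,B));"
        a = stats.abouheif(self.TREE, self.TRAIT, method="exhaustive")
        b = stats.abouheif(tree2, self.TRAIT, method="exhaustive")
        assert a.c_stat == pytest.approx(b.c_stat)

    def test_affine_invariance_of_p(self):
        scaled = 3.5 * self.TRAIT + 11.0
        a = stats.abouheif(self.TREE, self.TRAIT, n_perm=199, seed=2)
        b = stats.abouheif(self.TREE, scaled, n_perm=199, seed=2)
        assert a.c_stat == pytest.approx(b.c_stat)
        assert a.p == b.p

    def test_constant_trait_rejected(self):
        const = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("ABCD"))
        with pytest.raises(ValueError, match="constant"):
            stats.abouheif(self.TREE, const, n_perm=199)

    def test_null_type_one_error_calibrated(self):
        """Type-I error at alpha = 0.05 under the permutation null stays
        inside the binomial 95% band over 200 replicates."""
        from hoverstab.synthetic import TreeParams, gen_tree_with_trait

        rejections = 0
        for i in range(200):
            nw, tr = gen_tree_with_trait(
                SyntheticPlan(seed=5000 + i, tree_params=TreeParams(n_taxa=13))
            )
            rejections += stats.abouheif(nw, tr, n_perm=199, seed=i).p <= 0.05
        # Binomial(200, 0.05): central 95% mass within [4, 17]
        assert 4 <= rejections <= 17
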