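import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from rehoscales.assoc import (
    adjusted_ttest,
    bonferroni_threshold,
    chi_square_counts,
    compare_demographics,
    ks_normality,
    me_t_correlation,
    sphere_sample_t,
)


class TestKSNormality:
    def test_deterministic_given_seed(self):
        x = np.random.default_rng(0).standard_normal(100)
        assert ks_normality(x, seed=5) == ks_normality(x, seed=5)

    def test_constant_input_gives_zero(self):
        assert ks_normality(np.ones(20)) == 0.0

    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(12).standard_normal(500)
        assert ks_normality(x, seed=42) > 0.05

    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(1).exponential(size=500)
        assert ks_normality(x, seed=42) < 0.05

    def test_small_sample_refused(self):
        with pytest.raises(ValueError):
            ks_normality(np.arange(5.0))


class TestAdjustedTTest:
    def test_orthogonal_covariates_reduce_to_pooled_t(self):
        rng = np.random.default_rng(2)
        n = 40
        group = np.repeat([0.0, 1.0], n // 2)
        # covariates orthogonal to both group and outcome contribute nothing
        y = rng.standard_normal(n)
        base = np.column_stack([np.ones(n), group, y])
        raw_cov = rng.standard_normal((n, 2))
        cov = raw_cov - base @ np.linalg.lstsq(base, raw_cov, rcond=None)[0]
        t_adj, _ = adjusted_ttest(y, group, cov)
        t_pooled, _ = stats.ttest_ind(y[group == 1], y[group == 0], equal_var=True)
        # same coefficient and SSR; only the residual df differs (n-4 vs n-2)
        assert t_adj == pytest.approx(t_pooled * np.sqrt((n - 4) / (n - 2)), abs=1e-8)

    def test_strong_group_signal_is_significant(self):
        rng = np.random.default_rng(3)
        group = np.repeat([0.0, 1.0], 10)
        y = group + 1e-4 * rng.standard_normal(20)
        _, p = adjusted_ttest(y, group, rng.standard_normal((20, 2)))
        assert p < 1e-6

    def test_matches_ols_oracle_n8(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(8)
        group = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        cov = rng.standard_normal((8, 2))
        t, p = adjusted_ttest(y, group, cov)
        fit = sm.OLS(y, sm.add_constant(np.column_stack([group, cov]))).fit()
        assert t == pytest.approx(fit.tvalues[1])
        assert p == pytest.approx(fit.pvalues[1])

    def test_vectorised_over_units(self):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((30, 4))
        group = np.repeat([0.0, 1.0], 15)
        cov = rng.standard_normal((30, 2))
        t_vec, p_vec = adjusted_ttest(Y, group, cov)
        for j in range(4):
            t_j, p_j = adjusted_ttest(Y[:, j], group, cov)
            assert t_vec[j] == pytest.approx(t_j)
            assert p_vec[j] == pytest.approx(p_j)

    def test_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(24)
        group = np.repeat([0.0, 1.0], 12)
        cov = rng.standard_normal((24, 2))
        t1, _ = adjusted_ttest(y, group, cov)
        t2, _ = adjusted_ttest(y, group, cov * np.array([100.0, 0.01]) + 7.0)
        assert t1 == pytest.approx(t2)


class TestBonferroni:
    @pytest.mark.parametrize(
        "m, printed, tol",
        [(272, 1.83e-4, 1e-6), (54, 9.3e-4, 5e-6), (17, 0.0029, 5e-5)],
    )
    def test_published_thresholds(self, m, printed, tol):
        # printed values are truncated to 2-3 significant figures
        assert bonferroni_threshold(0.05, m) == pytest.approx(printed, abs=tol)

    def test_single_test_returns_alpha(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestSphereExtraction:
    AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm voxels at the origin corner

    def test_tiny_radius_returns_single_voxel_value(self):
        rng = np.random.default_rng(7)
        vol = rng.standard_normal((5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        coords = np.array([[4.0, 6.0, 2.0]])  # voxel (2, 3, 1)
        out = sphere_sample_t(vol, self.AFFINE, mask, coords, radius=0.5)
        assert out[0] == pytest.approx(vol[2, 3, 1])

    def test_midpoint_sample_averages_two_voxels(self):
        vol = np.zeros((4, 4, 4))
        vol[1, 1, 1] = 1.0
        vol[2, 1, 1] = 3.0
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = mask[2, 1, 1] = True
        coords = np.array([[3.0, 2.0, 2.0]])  # midway between the two centres
        out = sphere_sample_t(vol, self.AFFINE, mask, coords, radius=1.2)
        assert out[0] == pytest.approx(2.0)

    def test_constant_map_returns_constant(self):
        vol = np.full((6, 6, 6), 3.7)
        mask = np.ones((6, 6, 6), bool)
        rng = np.random.default_rng(8)
        coords = rng.uniform(2, 8, size=(5, 3))
        out = sphere_sample_t(vol, self.AFFINE, mask, coords, radius=6.0)
        assert np.allclose(out, 3.7)

    def test_matches_brute_force_voxel_search(self):
        rng = np.random.default_rng(9)
        vol = rng.standard_normal((6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.3
        coords = rng.uniform(0, 10, size=(4, 3))
        out = sphere_sample_t(vol, self.AFFINE, mask, coords, radius=4.0)
        for s, pt in enumerate(coords):
            acc = []
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        if not mask[i, j, k]:
                            continue
                        centre = self.AFFINE[:3, :3] @ [i, j, k] + self.AFFINE[:3, 3]
                        if np.linalg.norm(centre - pt) <= 4.0:
                            acc.append(vol[i, j, k])
            if acc:
                assert out[s] == pytest.approx(np.mean(acc))
            else:
                assert np.isnan(out[s])

    def test_uncovered_sample_is_nan(self):
        vol = np.zeros((4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        out = sphere_sample_t(vol, self.AFFINE, mask, np.array([[99.0, 99.0, 99.0]]), radius=2.0)
        assert np.isnan(out[0])


class TestMETCorrelation:
    @staticmethod
    def table(me_rows, t, compartments):
        me = pd.DataFrame(me_rows, index=[f"m{i + 1}" for i in range(len(me_rows))])
        return me_t_correlation(me, np.asarray(t, float), np.asarray(compartments))

    def test_identical_vectors_give_unit_correlation(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = self.table([t], t, ["cortical"] * 5)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_hand_covariance_formula(self):
        me = np.array([0.5, -1.0, 2.0, 1.0, -0.5])
        t = np.array([1.0, 0.0, 3.0, 2.0, 1.0])
        out = self.table([me], t, ["cortical"] * 5)
        r_hand = np.corrcoef(me, t)[0, 1]
        assert out.loc[0, "r"] == pytest.approx(r_hand)

    def test_compartments_analysed_separately_with_bh_within(self):
        rng = np.random.default_rng(10)
        n = 30
        t = rng.standard_normal(n)
        compartments = np.array(["cortical"] * 15 + ["subcortical"] * 15)
        me_rows = [t + 0.1 * rng.standard_normal(n), rng.standard_normal(n)]
        out = self.table(me_rows, t, compartments)
        assert set(out["compartment"]) == {"cortical", "subcortical"}
        for comp in ("cortical", "subcortical"):
            sub = out[out["compartment"] == comp]
            assert (sub["q"] >= sub["p"] - 1e-12).all()
            assert len(sub) == 2

    def test_affine_transform_flips_sign_only(self):
        rng = np.random.default_rng(11)
        me = rng.standard_normal(12)
        t = me + 0.2 * rng.standard_normal(12)
        r_pos = self.table([me], t, ["c"] * 12).loc[0, "r"]
        r_neg = self.table([-3.0 * me + 1.0], t, ["c"] * 12).loc[0, "r"]
        assert r_neg == pytest.approx(-r_pos)

    def test_small_compartment_omitted(self):
        out = self.table([[1.0, 2.0, 3.0]], [1.0, 2.0, 3.0], ["a", "a", "b"])
        assert len(out) == 0 or set(out["compartment"]) == set()


class TestDemographics:
    def test_published_sex_table_chi_square(self):
        # patients 54 M / 49 F, controls 45 M / 65 F -> p = 0.092
        chi2, p = chi_square_counts([[54, 49], [45, 65]])
        assert round(p, 3) == 0.092

    def test_balanced_table_gives_chi2_zero(self):
        chi2, p = chi_square_counts([[50, 50], [50, 50]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_value(self):
        # expected counts all 5 -> chi2 = 4 * 25 / 5 = 20
        chi2, _ = chi_square_counts([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_counts([[0, 0], [5, 5]])

    def test_table_interface_runs_both_tests(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame(
            {
                "group": np.repeat([1, 0], 20),
                "age": rng.normal(34, 10, 40),
                "sex": rng.integers(0, 2, 40),
            }
        )
        out = compare_demographics(table)
        assert list(out["variable"]) == ["age", "sex"]
        t_sp, p_sp = stats.ttest_ind(
            table.loc[table["group"] == 1, "age"],
            table.loc[table["group"] == 0, "age"],
            equal_var=True,
        )
        assert out.loc[0, "p"] == pytest.approx(p_sp)
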