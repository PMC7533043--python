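import numpy as np
import pytest
from scipy.stats import binom

from facsex.individual_variation import (
    covariate_correlation,
    group_difference_test,
    ratio_randomization_test,
    sign_test_p,
    variance_randomization_test,
)

from conftest import make_derived_matrix


class TestVarianceRandomization:
    def test_saturated_sites_uninformative(self):
        dm = make_derived_matrix(np.ones((5, 20)))
        res = variance_randomization_test(dm, "P", n_permutations=200, seed=0)
        assert res.observed == 0.0
        assert (res.null_distribution == 0).all()
        assert res.p_value == 1.0

    def test_extreme_concentration_smallest_p(self):
        mat = np.zeros((10, 50), dtype=np.uint8)
        mat[0] = 1  # one strain carries all 50 singletons
        res = variance_randomization_test(make_derived_matrix(mat), "P", seed=3)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_type_one_error_calibration(self):
        """Null-generated carriers: rejection rate at alpha=0.05 stays
        near nominal over 200 replicate datasets."""
        rng = np.random.default_rng(17)
        rejections = 0
        for _ in range(200):
            n, m = 10, 60
            k = rng.integers(1, n, size=m)
            mat = np.zeros((n, m), dtype=np.uint8)
            for j, kk in enumerate(k):
                mat[rng.choice(n, kk, replace=False), j] = 1
            res = variance_randomization_test(
                make_derived_matrix(mat), "P", n_permutations=400,
                seed=int(rng.integers(2**31)),
            )
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / 200 <= 0.09

    def test_bit_reproducible_given_seed(self):
        rng = np.random.default_rng(4)
        mat = (rng.random((8, 40)) < 0.3).astype(np.uint8)
        mat[:, mat.sum(axis=0) == 0] = 1
        a = variance_randomization_test(make_derived_matrix(mat), "P", seed=99)
        b = variance_randomization_test(make_derived_matrix(mat), "P", seed=99)
        assert a.p_value == b.p_value
        assert (a.null_distribution == b.null_distribution).all()

    def test_invariant_to_column_order_and_monomorphic_columns(self):
        rng = np.random.default_rng(6)
        mat = (rng.random((8, 30)) < 0.4).astype(np.uint8)
        obs1 = variance_randomization_test(make_derived_matrix(mat), "P", seed=1).observed
        perm = rng.permutation(30)
        obs2 = variance_randomization_test(make_derived_matrix(mat[:, perm]), "P", seed=1).observed
        padded = np.hstack([mat, np.zeros((8, 10), dtype=np.uint8)])
        obs3 = variance_randomization_test(make_derived_matrix(padded), "P", seed=1).observed
        assert obs1 == obs2 == obs3

    def test_no_derived_alleles_rejected(self):
        with pytest.raises(ValueError):
            variance_randomization_test(make_derived_matrix(np.zeros((4, 5))), "P")


class TestRatioRandomization:
    def test_identical_rows_give_p_one(self, pipeline):
        table = pipeline["table"]
        coords = np.concatenate([
            np.flatnonzero(table.class_mask("0fold"))[:30],
            np.flatnonzero(table.class_mask("4fold"))[:30],
        ])
        mat = np.tile((np.arange(60) % 2).astype(np.uint8), (6, 1))
        dm = make_derived_matrix(mat)
        dm.site_coords = coords
        res = ratio_randomization_test(dm, table, "P", n_permutations=100, seed=1)
        assert res.p_value == 1.0

    def test_zero_four_fold_strain_excluded(self, pipeline):
        table = pipeline["table"]
        dm = pipeline["derived"]
        # zero one strain's 4-fold row to force exclusion
        mask4 = table.class_mask("4fold")[dm.site_coords]
        mat = dm.matrix.copy()
        mat[0, mask4] = 0
        dm2 = make_derived_matrix(mat)
        dm2.site_coords = dm.site_coords
        with pytest.warns(UserWarning, match="zero 4-fold"):
            res = ratio_randomization_test(dm2, table, "P", n_permutations=50, seed=2)
        assert res.excluded_strains == ("s0",)

    def test_uniform_p_under_null(self, pipeline):
        """Equal selection across strains: the ratio-variance test p-values
        are approximately uniform (KS, alpha=0.01)."""
        from scipy.stats import kstest

        table = pipeline["table"]
        coords = pipeline["derived"].site_coords
        mask0 = table.class_mask("0fold")[coords]
        mask4 = table.class_mask("4fold")[coords]
        rng = np.random.default_rng(23)
        pvals = []
        for _ in range(120):
            n = 8
            mat = np.zeros((n, len(coords)), dtype=np.uint8)
            for j in np.flatnonzero(mask0 | mask4):
                k = rng.integers(1, n)
                mat[rng.choice(n, k, replace=False), j] = 1
            dm = make_derived_matrix(mat)
            dm.site_coords = coords
            res = ratio_randomization_test(dm, table, "P", n_permutations=99,
                                           seed=int(rng.integers(2**31)))
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestGroupDifference:
    def test_identical_profiles_p_one(self):
        totals = [5.0] * 8
        labels = ["x"] * 4 + ["y"] * 4
        res = group_difference_test(totals, labels, n_permutations=200, seed=0)
        assert res.p_value == 1.0

    def test_extreme_separation(self):
        # ties arise whenever a permutation redraws the same partition, so
        # the attainable minimum p is (1 + #partition recurrences)/(1 + N)
        totals = [0.0] * 5 + [1000.0] * 5
        labels = ["a"] * 5 + ["b"] * 5
        res = group_difference_test(totals, labels, seed=1)
        assert res.p_value <= 0.02

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(12)
        rej = 0
        for _ in range(200):
            totals = rng.normal(100, 10, size=12)
            labels = np.array(["a"] * 6 + ["b"] * 6)
            rng.shuffle(labels)
            res = group_difference_test(totals, labels, n_permutations=200,
                                        seed=int(rng.integers(2**31)))
            rej += res.p_value <= 0.05
        assert 0.01 <= rej / 200 <= 0.10

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_difference_test([1, 2, 3], ["a", "a", "b"])


class TestCovariateCorrelation:
    def test_self_correlation_is_one(self):
        totals = np.arange(10, dtype=float)
        out = covariate_correlation(totals, totals)
        assert out["r"] == pytest.approx(1.0)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            covariate_correlation([1.0, 2, 3], [5.0, 5, 5])

    def test_sign_test_matches_exact_binomial(self):
        # full sweep over k for n <= 20 against direct tail enumeration
        for n in range(1, 21):
            for k in range(0, n + 1):
                exact = sum(binom.pmf(j, n, 0.5) for j in range(k, n + 1))
                assert sign_test_p(k, n) == pytest.approx(exact, abs=1e-12)

    def test_thirteen_of_sixteen(self):
        assert sign_test_p(13, 16) == pytest.approx(697 / 65536)
        assert sign_test_p(13, 16) == pytest.approx(0.0106, abs=2e-4)
        assert sign_test_p(8, 16) == pytest.approx(0.598, abs=1e-3)

    def test_per_chromosome_concordance(self):
        rng = np.random.default_rng(3)
        lat = np.linspace(35, 55, 12)
        per_chrom = {f"chr{i}": -lat + rng.normal(0, 1, 12) for i in range(6)}
        totals = sum(per_chrom.values())
        out = covariate_correlation(totals, lat, per_chromosome_totals=per_chrom)
        assert out["r"] < 0
        assert out["n_concordant"] == 6
        assert out["sign_test_p"] == pytest.approx(sign_test_p(6, 6))
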