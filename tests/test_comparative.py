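"""Count matrices, normality-gated group comparisons, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tapkit.comparative import (
    CountMatrix,
    build_count_matrix,
    compare_groups,
    exact_rank_sum_p,
    run_pca,
    select_families_with_presence,
)


def cm(grid, families, species):
    return CountMatrix(pd.DataFrame(grid, index=families, columns=species))


class TestBuildCountMatrix:
    def test_zero_fill_for_disjoint_families(self):
        matrix = build_count_matrix({"S1": {"A": 2}, "S2": {"B": 3}})
        assert matrix.data.loc["A", "S2"] == 0
        assert matrix.data.loc["B", "S1"] == 0
        assert matrix.families == ["A", "B"]
        assert matrix.species == ["S1", "S2"]

    def test_empty_profiles(self):
        matrix = build_count_matrix({})
        assert matrix.species == []

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            build_count_matrix({"S1": {"A": -1}})

    def test_family_universe_fixes_rows(self):
        matrix = build_count_matrix({"S1": {"A": 1}}, family_universe=["B", "A"])
        assert matrix.families == ["B", "A"]
        assert matrix.data.loc["B", "S1"] == 0

    def test_tsv_round_trip(self, tmp_path):
        matrix = build_count_matrix({"S1": {"A": 2, "B": 1}, "S2": {"A": 4}})
        path = tmp_path / "m.tsv"
        matrix.to_tsv(path)
        back = CountMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(matrix.data, back.data)


class TestPresenceFilter:
    def test_all_zero_family_dropped_and_singleton_kept(self):
        matrix = cm([[0, 0, 5], [1, 0, 0]], ["dropme", "keepme"], ["F1", "F2", "OUT"])
        out = select_families_with_presence(matrix, ["F1", "F2"])
        assert out.families == ["keepme"]
        assert out.species == ["F1", "F2", "OUT"]

    def test_unknown_focal_species_rejected(self):
        matrix = cm([[1]], ["A"], ["S1"])
        with pytest.raises(KeyError):
            select_families_with_presence(matrix, ["nope"])

    def test_matches_per_row_any_oracle(self):
        rng = np.random.default_rng(42)
        grid = rng.integers(0, 3, size=(30, 8))
        families = [f"F{i}" for i in range(30)]
        species = [f"S{j}" for j in range(8)]
        matrix = cm(grid, families, species)
        focal = ["S1", "S4", "S6"]
        out = select_families_with_presence(matrix, focal)
        focal_idx = [species.index(s) for s in focal]
        expected = [
            fam for i, fam in enumerate(families) if any(grid[i, j] >= 1 for j in focal_idx)
        ]
        assert out.families == expected

    def test_idempotent_and_permutation_commuting(self):
        rng = np.random.default_rng(7)
        grid = rng.integers(0, 2, size=(12, 6))
        species = [f"S{j}" for j in range(6)]
        matrix = cm(grid, [f"F{i}" for i in range(12)], species)
        focal = ["S0", "S3"]
        once = select_families_with_presence(matrix, focal)
        twice = select_families_with_presence(once, focal)
        pd.testing.assert_frame_equal(once.data, twice.data)
        perm = ["S3", "S5", "S0", "S1", "S4", "S2"]
        permuted = CountMatrix(matrix.data[perm])
        out_perm = select_families_with_presence(permuted, focal)
        assert out_perm.families == once.families


class TestExactRankSum:
    def test_enumeration_reference_case(self):
        # most extreme separation of 3 vs 3: 2 of the C(6,3)=20 rank splits
        assert exact_rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_symmetry_in_group_order(self):
        a, b = [3.0, 9.0, 4.5, 7.0], [1.0, 2.0, 8.0]
        assert exact_rank_sum_p(a, b) == pytest.approx(exact_rank_sum_p(b, a))

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.permutation(np.arange(1, 13))[:5].astype(float)
            b = np.setdiff1d(np.arange(1, 13), a)[:5].astype(float)
            expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert exact_rank_sum_p(a, b) == pytest.approx(expected)

    def test_ties_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            exact_rank_sum_p([1, 1], [2, 3])


class TestCompareGroups:
    def matrix(self, values_a, values_b, family="C2H2"):
        species = [f"A{i}" for i in range(len(values_a))] + [
            f"B{i}" for i in range(len(values_b))
        ]
        return (
            cm([list(values_a) + list(values_b)], [family], species),
            [f"A{i}" for i in range(len(values_a))],
            [f"B{i}" for i in range(len(values_b))],
        )

    def test_identical_constant_groups_give_p_one(self):
        matrix, ga, gb = self.matrix([2, 2, 2], [2, 2, 2])
        res = compare_groups(matrix, "C2H2", ga, gb)
        assert res.p_value == 1.0
        assert res.degenerate
        assert res.test_used == "Wilcoxon"

    def test_large_planted_shift_detected(self):
        matrix, ga, gb = self.matrix([1, 2, 3, 1, 2], [20, 25, 30, 22, 28])
        res = compare_groups(matrix, "C2H2", ga, gb)
        assert res.p_value < 0.05

    def test_exact_route_for_small_tie_free_groups(self):
        matrix, ga, gb = self.matrix([1, 2, 3], [4, 5, 6])
        # alpha_normality=1.0 forces the rank-sum route regardless of the gate
        res = compare_groups(matrix, "C2H2", ga, gb, alpha_normality=1.0)
        assert res.test_used == "Wilcoxon"
        assert res.p_value == pytest.approx(0.1)

    def test_group_relabeling_invariance(self):
        matrix, ga, gb = self.matrix([3, 7, 5, 9], [2, 4, 1, 8])
        r1 = compare_groups(matrix, "C2H2", ga, gb)
        r2 = compare_groups(matrix, "C2H2", gb, ga)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.test_used == r2.test_used

    def test_total_sums_families_per_species(self):
        grid = [[1, 2, 3, 10, 11, 12], [1, 1, 2, 10, 12, 14]]
        species = ["a0", "a1", "a2", "b0", "b1", "b2"]
        matrix = cm(grid, ["F1", "F2"], species)
        res = compare_groups(matrix, "total", ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        # totals: 2,3,5 vs 20,23,26 -- the most extreme split
        assert res.p_value < 0.2

    def test_overlapping_groups_rejected(self):
        matrix, ga, gb = self.matrix([1, 2, 3], [4, 5, 6])
        with pytest.raises(ValueError, match="disjoint"):
            compare_groups(matrix, "C2H2", ga, ga)

    def test_t_test_route_on_normal_data(self):
        rng = np.random.default_rng(3)
        va = rng.normal(10, 1, 8).round(2)
        vb = rng.normal(10.5, 1, 8).round(2)
        matrix, ga, gb = self.matrix(va, vb)
        res = compare_groups(matrix, "C2H2", ga, gb)
        if res.test_used == "t-test":
            expected = stats.ttest_ind(va, vb, equal_var=False).pvalue
            assert res.p_value == pytest.approx(expected)
        else:  # normality gate decided otherwise; route must be consistent
            assert res.normality_p <= 0.05


class TestPCA:
    def test_single_varying_family_concentrates_variance(self):
        grid = [[1, 5, 9], [2, 2, 2], [7, 7, 7]]
        matrix = cm(grid, ["V", "C1", "C2"], ["S1", "S2", "S3"])
        res = run_pca(matrix)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_rank_two_matrix_has_two_nonzero_fractions(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(6, 1))
        v = rng.normal(size=(1, 10))
        u2 = rng.normal(size=(6, 1))
        v2 = rng.normal(size=(1, 10))
        X = 5 * u @ v + 3 * u2 @ v2
        X = np.round(X - X.min()).astype(int)  # non-negative integer counts
        matrix = cm(X.T, [f"F{i}" for i in range(10)], [f"S{j}" for j in range(6)])
        res = run_pca(matrix)
        # independent oracle: eigenvalues of the covariance of centered data
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Xc.T)))[::-1]
        rank = int((eig > 1e-8 * eig[0]).sum())
        nonzero = int((res.variance_fraction > 1e-8).sum())
        assert nonzero == rank
        expected = eig[: len(res.variance_fraction)] / eig.sum()
        np.testing.assert_allclose(res.variance_fraction, expected, atol=1e-10)

    def test_variance_fractions_sum_to_one_and_non_increasing(self):
        rng = np.random.default_rng(2)
        grid = rng.integers(0, 9, size=(15, 7))
        matrix = cm(grid, [f"F{i}" for i in range(15)], [f"S{j}" for j in range(7)])
        res = run_pca(matrix)
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)

    def test_scores_invariant_under_family_reordering(self):
        rng = np.random.default_rng(5)
        grid = rng.integers(0, 9, size=(10, 6))
        families = [f"F{i}" for i in range(10)]
        species = [f"S{j}" for j in range(6)]
        matrix = cm(grid, families, species)
        perm = rng.permutation(10)
        shuffled = CountMatrix(matrix.data.iloc[perm])
        r1, r2 = run_pca(matrix), run_pca(shuffled)
        np.testing.assert_allclose(r1.scores.values, r2.scores.values, atol=1e-8)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(8)
        grid = rng.integers(0, 9, size=(12, 5))
        matrix = cm(grid, [f"F{i}" for i in range(12)], [f"S{j}" for j in range(5)])
        res = run_pca(matrix)
        X = matrix.data.to_numpy(dtype=float).T
        Xc = X - X.mean(axis=0)
        recon = res.scores.values @ res.loadings.values.T
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_single_species_rejected(self):
        matrix = cm([[1]], ["A"], ["S1"])
        with pytest.raises(ValueError, match="2 species"):
            run_pca(matrix)
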