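"""Level covariances, eigendecomposition, model building, partitioning."""

import numpy as np
import pandas as pd
import pytest

import morphpca as mp
from morphpca.model import LevelComponent, MultilevelPCAResults

from conftest import balanced_dataset


class TestGrandMean:
    def test_single_row(self):
        X = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(mp.grand_mean(X), X[0])

    def test_opposite_rows_cancel(self, rng):
        v = rng.normal(size=5)
        np.testing.assert_allclose(
            mp.grand_mean(np.stack([v, -v])), np.zeros(5), atol=1e-15
        )

    def test_matches_streaming_mean_oracle(self, rng):
        X = rng.normal(size=(1000, 7))
        acc = np.zeros(7)
        for i, row in enumerate(X, start=1):
            acc += (row - acc) / i  # one-pass streaming update
        np.testing.assert_allclose(mp.grand_mean(X), acc, atol=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mp.grand_mean(np.empty((0, 3)))


class TestFactorLevelCovariance:
    def test_identical_group_means_give_zero(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        cov = mp.factor_level_covariance(X, ["a", "a", "b", "b"])
        np.testing.assert_allclose(cov, 0.0, atol=1e-15)

    def test_scalar_two_group_value(self):
        # group means -1 and +1; unweighted centre 0; divisor G=2
        X = np.array([[-1.0], [-1.0], [1.0]])
        cov = mp.factor_level_covariance(X, ["a", "a", "b"])
        np.testing.assert_allclose(cov, [[1.0]], atol=1e-15)

    def test_three_groups_rank_at_most_two(self, rng):
        X = rng.normal(size=(30, 6))
        groups = np.repeat(["a", "b", "c"], 10)
        cov = mp.factor_level_covariance(X, groups)
        eig = np.linalg.eigvalsh(cov)
        assert np.sum(eig > 1e-10) <= 2

    def test_unweighted_against_imbalance(self, rng):
        # enlarging one group must not change its weight in the level
        mean_a, mean_b = np.array([1.0, 0.0]), np.array([-1.0, 0.0])
        small = np.vstack([np.tile(mean_a, (5, 1)), np.tile(mean_b, (5, 1))])
        big = np.vstack([np.tile(mean_a, (50, 1)), np.tile(mean_b, (5, 1))])
        cov_small = mp.factor_level_covariance(
            small, ["a"] * 5 + ["b"] * 5
        )
        cov_big = mp.factor_level_covariance(big, ["a"] * 50 + ["b"] * 5)
        np.testing.assert_allclose(cov_small, cov_big, atol=1e-12)

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="two non-empty groups"):
            mp.factor_level_covariance(np.ones((3, 2)), ["a", "a", "a"])


class TestSubjectLevelCovariance:
    def test_single_cell_equals_within_covariance(self, rng):
        X = rng.normal(size=(20, 4))
        cov, skipped = mp.subject_level_covariance(X, ["c"] * 20)
        dev = X - X.mean(axis=0)
        np.testing.assert_allclose(cov, dev.T @ dev / 20, atol=1e-12)
        assert skipped == []

    def test_identical_cell_covariances_pass_through(self):
        base = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0], [0.0, -2.0]])
        X = np.vstack([base + 10 * i for i in range(3)])
        cells = np.repeat(["a", "b", "c"], 4)
        cov, _ = mp.subject_level_covariance(X, cells)
        dev = base - base.mean(axis=0)
        np.testing.assert_allclose(cov, dev.T @ dev / 4, atol=1e-12)

    def test_scalar_median_over_cells(self):
        # three scalar cells with population variances 1, 1, 100
        cells_data = [
            np.array([[-1.0], [1.0]]),
            np.array([[-1.0], [1.0]]),
            np.array([[-10.0], [10.0]]),
        ]
        X = np.vstack(cells_data)
        cells = np.repeat(["a", "b", "c"], 2)
        cov, _ = mp.subject_level_covariance(X, cells)
        np.testing.assert_allclose(cov, [[1.0]], atol=1e-12)

    def test_small_cells_skipped_and_reported(self, rng):
        X = rng.normal(size=(5, 2))
        cells = ["a", "a", "a", "a", "lonely"]
        cov, skipped = mp.subject_level_covariance(X, cells)
        assert skipped == ["lonely"]

    def test_all_singleton_cells_raise(self):
        with pytest.raises(ValueError, match="at least two"):
            mp.subject_level_covariance(np.ones((3, 2)), ["a", "b", "c"])

    def test_median_robust_to_one_inflated_cell(self, rng):
        # >= 3 other cells share the median, so inflating one changes nothing
        base = rng.normal(size=(6, 3))
        X = np.vstack([base] * 4 + [base * 100.0])
        cells = np.repeat(list("abcde"), 6)
        ref, _ = mp.subject_level_covariance(np.vstack([base] * 5), cells)
        inflated, _ = mp.subject_level_covariance(X, cells)
        assert np.max(np.abs(inflated - ref)) < 1e-9


class TestEigendecomposeLevel:
    def test_identity_matrix(self):
        comp = mp.eigendecompose_level(np.eye(3), "sex", 2, 2)
        np.testing.assert_allclose(comp.eigenvalues, [1.0, 1.0, 1.0])
        assert comp.retained == 2

    def test_diagonal_matrix_and_sign_convention(self):
        comp = mp.eigendecompose_level(np.diag([4.0, 1.0]), "sex", 2, 1)
        assert comp.eigenvalues[0] == pytest.approx(4.0)
        np.testing.assert_allclose(comp.eigenvectors[:, 0], [1.0, 0.0])

    def test_matches_characteristic_polynomial_oracle(self, rng):
        A = rng.normal(size=(3, 3))
        cov = A @ A.T
        # independent oracle: roots of det(cov - lambda I) from the
        # analytic coefficients of the cubic characteristic polynomial
        tr = np.trace(cov)
        minors = (
            cov[1, 1] * cov[2, 2] - cov[1, 2] * cov[2, 1]
            + cov[0, 0] * cov[2, 2] - cov[0, 2] * cov[2, 0]
            + cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
        )
        det = np.linalg.det(cov)
        roots = np.sort(np.roots([1.0, -tr, minors, -det]).real)[::-1]
        comp = mp.eigendecompose_level(cov, "test", 4, 3)
        np.testing.assert_allclose(comp.eigenvalues, roots, atol=1e-9)

    def test_asymmetric_rejected(self):
        bad = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            mp.eigendecompose_level(bad, "sex", 2, 1)

    def test_retention_beyond_rank_bound_cites_rule(self):
        with pytest.raises(ValueError, match="groups minus 1"):
            mp.eigendecompose_level(np.eye(3), "sex", 2, 2, rank_bound=1)

    def test_negative_mass_clamped(self):
        cov = np.diag([2.0, -0.5])
        comp = mp.eigendecompose_level(cov, "subject", 3, 1)
        assert np.all(comp.eigenvalues >= 0)
        assert comp.clamped_mass == pytest.approx(0.5)


class TestBuildModel:
    def test_retention_capped_by_rank(self, tiny_data):
        dataset, _ = tiny_data
        res = mp.MultilevelPCA(dataset).fit(retain=(50, 50, 50, 50))
        caps = {c.level_name: c.retained for c in res.components}
        assert caps == {"smoking": 2, "alcohol": 2, "sex": 1, "subject": 9}

    def test_all_identical_rows_zero_eigenvalues(self):
        ds = balanced_dataset(2, seed=0)
        X = np.tile(np.arange(ds.p, dtype=float), (ds.n_subjects, 1))
        res = mp.MultilevelPCA(ds.with_coordinates(X)).fit(retain=(2, 2, 1, 5))
        for comp in res.components:
            np.testing.assert_allclose(comp.eigenvalues, 0.0, atol=1e-18)

    def test_eigenvector_orthonormality_within_levels(self, tiny_results):
        for comp in tiny_results.components:
            U = comp.eigenvectors
            np.testing.assert_allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-9)

    def test_sex_level_single_nonzero_eigenvalue(self, tiny_results):
        assert tiny_results.level("sex").n_nonzero <= 1

    def test_singleton_groups_reduce_to_conventional_pca(self, rng):
        """With one singleton-group level and constant factors, multilevel
        eigenanalysis must reproduce ordinary PCA."""
        X = rng.normal(size=(50, 9))
        labels = pd.DataFrame(
            {
                "smoking": ["none"] * 50,
                "alcohol": ["none"] * 50,
                "sex": ["male"] * 50,
                "id": [f"s{i}" for i in range(50)],
            }
        )
        levels = (mp.LevelSpec("subject", "between", ("id",)),)
        res = mp.MultilevelPCA(X, labels, levels=levels).fit(retain=(9,))
        comp, _, _ = mp.conventional_pca(X, 9)
        np.testing.assert_allclose(
            res.components[0].eigenvalues, comp.eigenvalues, atol=1e-8
        )

    def test_constant_factor_needs_explicit_permission(self, rng):
        X = rng.normal(size=(10, 3))
        labels = pd.DataFrame(
            {
                "smoking": ["none"] * 10,
                "alcohol": ["none"] * 10,
                "sex": ["male"] * 5 + ["female"] * 5,
            }
        )
        model = mp.MultilevelPCA(X, labels)
        with pytest.raises(ValueError, match="two non-empty groups"):
            model.fit(retain=(2, 2, 1, 3))
        res = model.fit(retain=(2, 2, 1, 3), allow_constant_factors=True)
        assert res.level("smoking").n_nonzero == 0


class TestVariancePartition:
    def test_single_level_fully_retained_is_total(self, rng):
        X = rng.normal(size=(30, 4))
        labels = pd.DataFrame({"id": [f"s{i}" for i in range(30)]})
        levels = (mp.LevelSpec("subject", "between", ("id",)),)
        res = mp.MultilevelPCA(X, labels, levels=levels).fit(retain=(4,))
        vp = res.variance_partition()
        assert vp["all_retained_pct"].iloc[0] == pytest.approx(100.0)

    def test_two_level_mass_split(self):
        """Fabricated eigenvalue masses 4 and 1 split 80/20."""
        comps = [
            LevelComponent("a", np.eye(2), np.array([3.0, 1.0]), 3, 2),
            LevelComponent("b", np.eye(2), np.array([1.0, 0.0]), 2, 1),
        ]
        dummy = mp.MultilevelPCA(
            np.zeros((1, 2)),
            pd.DataFrame({"g": ["x"]}),
            levels=(mp.LevelSpec("a", "between", ("g",)),),
        )
        res = MultilevelPCAResults(dummy, np.zeros(2), comps)
        vp = res.variance_partition().set_index("level")
        assert vp.loc["a", "all_retained_pct"] == pytest.approx(80.0)
        assert vp.loc["b", "all_retained_pct"] == pytest.approx(20.0)

    def test_retained_percent_sums_per_pc(self, tiny_results):
        vp = tiny_results.variance_partition()
        row = vp[vp["level"] == "smoking"].iloc[0]
        total = tiny_results.all_eigenvalues_total
        lam = tiny_results.level("smoking").retained_eigenvalues
        assert row["all_retained_pct"] == pytest.approx(
            100 * lam.sum() / total, abs=1e-9
        )
        assert row["pc1_pct"] + row["pc2_pct"] == pytest.approx(
            row["all_retained_pct"], abs=1e-9
        )

    def test_levels_sum_to_at_most_100(self, tiny_results):
        vp = tiny_results.variance_partition()
        assert vp["all_retained_pct"].sum() <= 100.0 + 1e-9

    def test_permutation_invariance(self, tiny_data, rng):
        dataset, _ = tiny_data
        perm = rng.permutation(dataset.n_subjects)
        shuffled = mp.ShapeDataset(
            dataset.flattened[perm],
            dataset.labels.iloc[perm],
            [dataset.subject_ids[i] for i in perm],
            dataset.landmark_names,
        )
        vp0 = mp.MultilevelPCA(dataset).fit().variance_partition()
        vp1 = mp.MultilevelPCA(shuffled).fit().variance_partition()
        np.testing.assert_allclose(
            vp0["all_retained_pct"], vp1["all_retained_pct"], atol=1e-9
        )

    def test_zero_mass_errors(self):
        ds = balanced_dataset(2, seed=1)
        X = np.zeros_like(ds.flattened)
        res = mp.MultilevelPCA(ds.with_coordinates(X)).fit(retain=(2, 2, 1, 4))
        with pytest.raises(ValueError, match="zero total"):
            res.variance_partition()


class TestConventionalPCA:
    def test_collinear_data_single_component(self, rng):
        direction = np.array([1.0, 2.0, -1.0])
        direction /= np.linalg.norm(direction)
        X = np.outer(rng.normal(size=40), direction)
        comp, scores, _ = mp.conventional_pca(X, 3)
        assert np.sum(comp.eigenvalues > 1e-12) == 1
        cross = abs(comp.eigenvectors[:, 0] @ direction)
        assert cross == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalue_sum_equals_trace(self, rng):
        X = rng.normal(size=(25, 6))
        comp, _, _ = mp.conventional_pca(X)
        dev = X - X.mean(axis=0)
        cov = dev.T @ dev / 25
        assert comp.eigenvalues.sum() == pytest.approx(
            np.trace(cov), abs=1e-9
        )

    def test_matches_power_iteration_oracle(self, rng):
        X = rng.normal(size=(200, 5))
        dev = X - X.mean(axis=0)
        cov = dev.T @ dev / 200
        # independent oracle: power iteration with deflation
        expected = []
        work = cov.copy()
        for _ in range(3):
            v = np.ones(5) / np.sqrt(5)
            for _ in range(10000):
                w = work @ v
                v = w / np.linalg.norm(w)
            lam = float(v @ work @ v)
            expected.append(lam)
            work = work - lam * np.outer(v, v)
        comp, _, _ = mp.conventional_pca(X, 3)
        np.testing.assert_allclose(
            comp.eigenvalues[:3], expected, atol=1e-6
        )

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            mp.conventional_pca(rng.normal(size=(4, 10)), 5)
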