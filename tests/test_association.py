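"""Per-category regression and flexible-beta clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from magprofiler import association as assoc
from magprofiler.core_io import ValidationError


def _ols_oracle(y, x1, x2):
    """Textbook two-predictor OLS: normal equations + t test for x1."""
    n = len(y)
    X = np.column_stack([np.ones(n), x1, x2])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - 3)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t = beta[1] / np.sqrt(cov[1, 1])
    p = 2 * stats.t.sf(abs(t), df=n - 3)
    return beta[1], p, beta[2]


class TestRegression:
    def test_exact_linear_case(self):
        counts = np.array([1.0, 2.0, 3.0, 4.0])
        trait = 0.5 * counts
        completeness = np.full(4, 80.0)
        r = assoc.fit_category_regression(trait, counts, completeness)
        assert r.fittable
        assert r.coefficient == pytest.approx(0.5, abs=1e-10)

    def test_planted_model_recovery(self):
        rng = np.random.default_rng(99)
        n = 200
        counts = rng.poisson(10, n).astype(float)
        completeness = rng.uniform(50, 100, n)
        trait = 0.3 * counts + 0.1 * completeness + rng.normal(0, 0.5, n)
        r = assoc.fit_category_regression(trait, counts, completeness)
        se_approx = 0.5 / (np.std(counts) * np.sqrt(n))
        assert abs(r.coefficient - 0.3) < 3 * se_approx
        assert r.p_value <= 0.05 and r.significant

    def test_null_type_i_calibration(self):
        """With no count effect, P <= 0.05 rejects ~5% of the time."""
        rng = np.random.default_rng(123)
        n, reps = 40, 1000
        rejections = 0
        for _ in range(reps):
            counts = rng.poisson(8, n).astype(float)
            completeness = rng.uniform(50, 100, n)
            trait = 0.1 * completeness + rng.normal(0, 1, n)
            r = assoc.fit_category_regression(trait, counts, completeness)
            rejections += r.significant
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_agrees_with_closed_form_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(5, 30))
            counts = rng.uniform(0, 20, n)
            completeness = rng.uniform(40, 100, n)
            trait = rng.normal(0, 1, n)
            r = assoc.fit_category_regression(trait, counts, completeness)
            b, p, cb = _ols_oracle(trait, counts, completeness)
            assert r.coefficient == pytest.approx(b, abs=1e-8)
            assert r.p_value == pytest.approx(p, abs=1e-8)
            assert r.completeness_coefficient == pytest.approx(cb, abs=1e-8)

    def test_constant_predictor_unfittable(self):
        r = assoc.fit_category_regression(
            [1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [80.0, 85.0, 90.0]
        )
        assert not r.fittable
        assert r.p_value is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            assoc.fit_category_regression([1.0, 2.0], [1.0, 2.0], [80.0, 80.0])


class TestFlexibleBeta:
    def test_two_leaves(self):
        d = assoc.beta_flexible_cluster(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert d.merges.shape == (1, 4)
        assert d.merges[0, 2] == pytest.approx(3.0)

    def test_hand_lance_williams_update(self):
        D = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        d = assoc.beta_flexible_cluster(D, beta=-0.25)
        assert d.merges[0, 2] == pytest.approx(1.0)
        # d({1,2},3) = 0.625*4 + 0.625*5 - 0.25*1
        assert d.merges[1, 2] == pytest.approx(5.375)

    def test_matches_brute_force_oracle(self, rng):
        """Merge heights equal a from-scratch recomputation that rebuilds the
        full cluster-distance table each step from the recurrence."""
        for _ in range(5):
            n = 6
            x = rng.uniform(0, 10, size=(n, 3))
            D = assoc.euclidean_distance_matrix(x)
            got = assoc.beta_flexible_cluster(D, beta=-0.25)
            expected_heights = _brute_force_heights(D, beta=-0.25)
            np.testing.assert_allclose(got.merges[:, 2], expected_heights, atol=1e-9)

    def test_beta_zero_equals_wpgma(self, rng):
        """Flexible beta at beta=0 reduces to WPGMA ('weighted' linkage)."""
        x = rng.uniform(0, 10, size=(8, 4))
        D = assoc.euclidean_distance_matrix(x)
        got = assoc.beta_flexible_cluster(D, beta=0.0)
        Z = linkage(squareform(D, checks=False), method="weighted")
        np.testing.assert_allclose(np.sort(got.merges[:, 2]), np.sort(Z[:, 2]), atol=1e-9)

    def test_monotone_heights_at_default_beta(self, rng):
        x = rng.uniform(0, 5, size=(12, 2))
        d = assoc.beta_flexible_cluster(assoc.euclidean_distance_matrix(x))
        heights = d.merges[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_leaf_relabeling_invariance(self, rng):
        x = rng.uniform(0, 10, size=(7, 3))
        D = assoc.euclidean_distance_matrix(x)
        perm = rng.permutation(7)
        Dp = D[np.ix_(perm, perm)]
        h1 = np.sort(assoc.beta_flexible_cluster(D).merges[:, 2])
        h2 = np.sort(assoc.beta_flexible_cluster(Dp).merges[:, 2])
        np.testing.assert_allclose(h1, h2, atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            assoc.beta_flexible_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_planted_two_cluster_recovery(self):
        """Two well-separated abundance profiles: perfect cut, R^2 > 0.95."""
        rng = np.random.default_rng(42)
        meso = rng.normal([5, 5, -5, -5], 0.3, size=(15, 4))
        thermo = rng.normal([-5, -5, 5, 5], 0.3, size=(15, 4))
        x = np.vstack([meso, thermo])
        d = assoc.beta_flexible_cluster(assoc.euclidean_distance_matrix(x))
        labels = assoc.cut_dendrogram(d, 2)
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
        assert labels[0] != labels[15]
        assert assoc.cluster_r2(labels, x) > 0.95


def _brute_force_heights(D, beta):
    """Independent Lance-Williams oracle keeping explicit cluster sets and a
    dict of pairwise distances rebuilt at each step."""
    alpha = (1 - beta) / 2
    clusters = [frozenset([i]) for i in range(D.shape[0])]
    dist = {
        (clusters[i], clusters[j]): D[i, j]
        for i in range(len(clusters))
        for j in range(i + 1, len(clusters))
    }

    def d_of(a, b):
        return dist.get((a, b), dist.get((b, a)))

    heights = []
    while len(clusters) > 1:
        best = min(
            (
                (d_of(clusters[i], clusters[j]), i, j)
                for i in range(len(clusters))
                for j in range(i + 1, len(clusters))
            ),
            key=lambda t: t[0],
        )
        h, i, j = best
        a, b = clusters[i], clusters[j]
        merged = a | b
        heights.append(h)
        new_clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        new_dist = {}
        for x in new_clusters:
            for y in new_clusters:
                if (x, y) in dist:
                    new_dist[(x, y)] = dist[(x, y)]
        for c in new_clusters:
            new_dist[(c, merged)] = alpha * d_of(c, a) + alpha * d_of(c, b) + beta * h
        clusters = new_clusters + [merged]
        dist = new_dist
    return heights


class TestClusterR2:
    def test_singletons_give_one(self):
        assert assoc.cluster_r2([0, 1, 2], [1.0, 5.0, 9.0]) == pytest.approx(1.0)

    def test_single_cluster_gives_zero(self):
        assert assoc.cluster_r2([0, 0, 0], [1.0, 5.0, 9.0]) == pytest.approx(0.0)

    def test_hand_computation(self):
        # {0,1 | 2,3}: SSB 4, SST 5
        assert assoc.cluster_r2([0, 0, 1, 1], [0.0, 1.0, 2.0, 3.0]) == pytest.approx(0.8)

    def test_zero_total_ss_warns(self):
        with pytest.warns(UserWarning):
            assert assoc.cluster_r2([0, 1], [2.0, 2.0]) == 0.0


class TestAssociateAll:
    def test_tidy_output_over_shared_pgs(self):
        rng = np.random.default_rng(3)
        pgs = [f"PG{i}" for i in range(30)]
        contrasts = pd.DataFrame(
            rng.normal(size=(30, 2)), index=pgs, columns=["mean_thermo_meso", "mean_post_pre"]
        )
        profiles = pd.DataFrame(
            rng.poisson(6, size=(30, 3)).astype(float), index=pgs, columns=["A", "B", "C"]
        )
        completeness = pd.Series(rng.uniform(50, 100, 30), index=pgs)
        out = assoc.associate_all(contrasts, profiles, completeness)
        assert len(out) == 6
        assert set(out["trait"]) == {"mean_thermo_meso", "mean_post_pre"}
        assert out["p_value"].between(0, 1).all()
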