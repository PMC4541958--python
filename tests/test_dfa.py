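import numpy as np
import pytest

from etongue.dfa import (
    DegenerateScatterError,
    classify_distance,
    discrimination_index,
    fit_dfa,
    project,
    RIDGE_EPS,
)


def eigen_oracle(X, y):
    """Brute-force generalized eigenvalues via explicit inverse (p <= 3)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, p = X.shape
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in np.unique(y):
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        Sw += (Xc - mu).T @ (Xc - mu)
        Sb += len(Xc) * np.outer(mu - grand, mu - grand)
    ridge = RIDGE_EPS * (np.trace(Sw) + np.trace(Sb)) / p
    vals = np.linalg.eigvals(np.linalg.inv(Sw + ridge * np.eye(p)) @ Sb)
    return np.sort(np.real(vals))[::-1]


@pytest.fixture
def three_class_instance():
    rng = np.random.default_rng(99)
    centers = np.array([[0.0, 0.0], [3.0, 1.0], [1.0, 4.0]])
    X = np.vstack([c + 0.3 * rng.normal(size=(15, 2)) for c in centers])
    y = np.repeat([1, 2, 3], 15)
    return X, y


class TestFitDfa:
    def test_matches_generalized_eigen_oracle(self, three_class_instance):
        X, y = three_class_instance
        model = fit_dfa(X, y)
        expected = eigen_oracle(X, y)[: model.eigenvalues.size]
        np.testing.assert_allclose(model.eigenvalues, expected, atol=1e-8)

    def test_eigenvalues_sorted_contribution_accumulates(self, three_class_instance):
        X, y = three_class_instance
        model = fit_dfa(X, y)
        assert np.all(model.eigenvalues >= 0)
        assert np.all(np.diff(model.eigenvalues) <= 0)
        assert model.accumulated_contribution[-1] == pytest.approx(1.0)

    def test_two_point_clusters_single_axis(self):
        # zero within-class variance: the regularized fit still finds the
        # single informative direction with all of the discrimination on it
        X = np.vstack([np.tile([0.0, 0.0], (5, 1)), np.tile([1.0, 2.0], (5, 1))])
        y = np.repeat([1, 2], 5)
        model = fit_dfa(X, y)
        assert model.accumulated_contribution[0] == pytest.approx(1.0)
        assert model.canonical_correlations[0] == pytest.approx(1.0, abs=1e-6)

    def test_permuted_labels_give_null_eigenvalues(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2000, 2))
        y = rng.integers(1, 5, size=2000)
        model = fit_dfa(X, y)
        assert np.all(model.eigenvalues < 0.05)

    def test_singleton_class_rejected(self):
        X = np.arange(10, dtype=float).reshape(5, 2)
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_dfa(X, [1, 1, 2, 2, 3])

    def test_identical_features_rejected(self):
        X = np.ones((8, 2))
        with pytest.raises(DegenerateScatterError):
            fit_dfa(X, [1, 1, 2, 2, 3, 3, 4, 4])

    def test_axis_signs_are_deterministic(self, three_class_instance):
        X, y = three_class_instance
        a = fit_dfa(X, y)
        b = fit_dfa(X, y)
        np.testing.assert_array_equal(a.axes, b.axes)
        for j in range(a.axes.shape[1]):
            col = a.axes[:, j]
            nz = np.flatnonzero(np.abs(col) > 1e-12 * np.abs(col).max())
            assert col[nz[0]] > 0


class TestProject:
    def test_centroids_project_onto_class_centroids(self, three_class_instance):
        X, y = three_class_instance
        model = fit_dfa(X, y)
        for i, c in enumerate(model.class_codes):
            got = project(model, X[y == c].mean(axis=0))[0]
            np.testing.assert_allclose(got, model.class_centroids[i, :2], atol=1e-10)

    def test_grand_centroid_projects_to_origin(self, three_class_instance):
        X, y = three_class_instance
        model = fit_dfa(X, y)
        np.testing.assert_allclose(project(model, X.mean(axis=0))[0], 0.0, atol=1e-10)

    def test_training_scores_reproduced(self, three_class_instance):
        X, y = three_class_instance
        model = fit_dfa(X, y)
        np.testing.assert_allclose(project(model, X), model.scores_2d, atol=1e-12)

    def test_dimension_mismatch(self, three_class_instance):
        X, y = three_class_instance
        model = fit_dfa(X, y)
        with pytest.raises(ValueError):
            project(model, np.zeros((2, 5)))


class TestClassifyDistance:
    def test_sample_at_centroid_gets_its_class(self, three_class_instance):
        X, y = three_class_instance
        model = fit_dfa(X, y)
        for i, c in enumerate(model.class_codes):
            mu = X[y == c].mean(axis=0)
            assert classify_distance(model, mu)[0] == c

    def test_equidistant_tie_breaks_to_lower_code(self):
        # mirror-symmetric classes 2 and 3 about x = 0; a probe at the grand
        # centroid is equidistant from both centroids
        X = np.array(
            [[-2.0, -1.0], [-2.0, 1.0], [2.0, -1.0], [2.0, 1.0]], dtype=float
        )
        y = np.array([2, 2, 3, 3])
        model = fit_dfa(X, y)
        assert classify_distance(model, X.mean(axis=0))[0] == 2

    def test_matches_exhaustive_nearest_centroid(self, three_class_instance):
        X, y = three_class_instance
        model = fit_dfa(X, y)
        scores = (X - model.grand_mean) @ model.axes
        expected = []
        for s in scores:
            d = [np.sum((s - c) ** 2) for c in model.class_centroids]
            expected.append(model.class_codes[int(np.argmin(d))])
        np.testing.assert_array_equal(classify_distance(model, X), expected)


class TestDiscriminationIndex:
    def test_perfect_separation_scores_100_exactly(self):
        X = np.vstack(
            [
                np.tile([0.0, 0.0], (5, 1)),
                np.tile([4.0, 0.0], (5, 1)),
                np.tile([0.0, 4.0], (5, 1)),
            ]
        )
        y = np.repeat([1, 2, 3], 5)
        model = fit_dfa(X, y)
        assert discrimination_index(model, X, y) == 100

    def test_unrelated_labels_score_near_zero(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(4000, 2))
        y = rng.integers(1, 5, size=4000)
        model = fit_dfa(X, y)
        assert discrimination_index(model, X, y) <= 2

    def test_zero_total_scatter_rejected(self, three_class_instance):
        X, y = three_class_instance
        model = fit_dfa(X, y)
        same = np.tile(X.mean(axis=0), (6, 1))
        with pytest.raises(DegenerateScatterError):
            discrimination_index(model, same, [1, 1, 2, 2, 3, 3])
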