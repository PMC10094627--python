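"""NIPALS PLS-DA against independent oracles, plus model invariants."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from aromakey import multivariate as mv
from aromakey.datamodel import ValidationError


class TestAutoscale:
    def test_hand_case(self):
        Xs, scaler = mv.autoscale(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(Xs[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_flagged(self):
        Xs, scaler = mv.autoscale(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        assert np.all(Xs[:, 1] == 0.0)
        assert list(scaler.zero_variance) == [False, True]

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(2)
        X = rng.lognormal(size=(20, 7))
        Xs, scaler = mv.autoscale(X)
        assert np.abs(scaler.inverse(Xs) - X).max() < 1e-10


class TestOneHot:
    def test_basic(self):
        Y = mv.one_hot(["a", "a", "b"], ["a", "b"])
        assert Y.tolist() == [[1, 0], [1, 0], [0, 1]]
        assert np.all(Y.sum(axis=1) == 1)

    def test_single_group_all_ones(self):
        assert mv.one_hot(["a", "a"], ["a"]).tolist() == [[1], [1]]

    def test_column_sums_are_group_sizes(self):
        Y = mv.one_hot(list("aabbbc"), ["a", "b", "c"])
        assert Y.sum(axis=0).tolist() == [2, 3, 1]

    def test_unknown_label(self):
        with pytest.raises(ValidationError, match="outside"):
            mv.one_hot(["a", "z"], ["a"])


def _random_problem(rng, n=30, p=12, groups=3, effect=4.0):
    labels = [f"g{i % groups}" for i in range(n)]
    X = rng.normal(size=(n, p))
    for i, lab in enumerate(labels):
        X[i, int(lab[1])] += effect
    Y = mv.one_hot(labels, [f"g{i}" for i in range(groups)])
    return X, Y, labels


class TestFit:
    def test_perfect_single_predictor(self):
        x = np.linspace(-1, 1, 12)[:, None]
        model = mv.fit_plsda_fixed(x, x.copy(), 1)
        assert model.r2y == pytest.approx(1.0, abs=1e-12)

    def test_first_weight_matches_dominant_eigenvector(self):
        """NIPALS w1 equals the top eigenvector of X'YY'X (dense oracle)."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            X = rng.normal(size=(6, 4))
            Y = rng.normal(size=(6, 2))
            model = mv.fit_plsda_fixed(X, Y, 1)
            Xs, _ = mv.autoscale(X)
            Yc = Y - Y.mean(axis=0)
            M = Xs.T @ Yc @ Yc.T @ Xs
            eigval, eigvec = np.linalg.eigh(M)
            w_oracle = eigvec[:, -1]
            w = model.weights[:, 0]
            if np.dot(w, w_oracle) < 0:
                w_oracle = -w_oracle
            assert np.abs(w - w_oracle).max() < 1e-6

    def test_matches_sklearn_first_component(self):
        """Cross-check against sklearn's NIPALS on pre-scaled data."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(15, 6))
        Y = rng.normal(size=(15, 3))
        Xs, _ = mv.autoscale(X)
        Yc = Y - Y.mean(axis=0)
        skl = PLSRegression(n_components=1, scale=False, tol=1e-12, max_iter=5000).fit(
            Xs, Yc
        )
        ours = mv.fit_plsda_fixed(X, Y, 1)
        w_skl = skl.x_weights_[:, 0]
        w = ours.weights[:, 0]
        if np.dot(w, w_skl) < 0:
            w_skl = -w_skl
        assert np.abs(w - w_skl).max() < 1e-6

    def test_noise_data_overfits_r2y_but_not_q2(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 10))
        labels = [f"g{i % 3}" for i in range(60)]
        Y = mv.one_hot(labels, ["g0", "g1", "g2"])
        r2 = [mv.fit_plsda_fixed(X, Y, a).r2y for a in (1, 3, 5)]
        assert r2[0] < r2[1] < r2[2]
        assert mv.cross_validated_q2(X, Y, 5, 7) <= 0.1

    def test_r2y_monotone_in_components(self):
        rng = np.random.default_rng(4)
        X, Y, _ = _random_problem(rng)
        r2 = [mv.fit_plsda_fixed(X, Y, a).r2y for a in range(1, 7)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_score_orthogonality_and_weight_norms(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            X, Y, _ = _random_problem(rng, n=24, p=9)
            model = mv.fit_plsda_fixed(X, Y, 4)
            T = model.scores
            for i in range(4):
                assert np.linalg.norm(model.weights[:, i]) == pytest.approx(1.0, abs=1e-8)
                for j in range(i):
                    bound = 1e-8 * np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j])
                    assert abs(T[:, i] @ T[:, j]) < max(bound, 1e-10)

    def test_component_truncation_warns(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 3))
        Y = mv.one_hot(list("aabab"), ["a", "b"])
        with pytest.warns(UserWarning, match="truncating"):
            model = mv.fit_plsda(X, Y, 10)
        assert model.n_components <= 3


class TestQ2:
    def test_separable_data_has_high_q2(self):
        """Two groups, large mean shift, tiny within-group noise."""
        rng = np.random.default_rng(8)
        n = 42
        X = 0.01 * rng.normal(size=(n, 10))
        labels = ["a" if i % 2 == 0 else "b" for i in range(n)]
        X[::2, 0] += 5.0
        Y = mv.one_hot(labels, ["a", "b"])
        assert mv.cross_validated_q2(X, Y, 2, 7) > 0.9

    def test_shuffled_labels_have_nonpositive_q2_in_expectation(self):
        rng = np.random.default_rng(9)
        vals = []
        for _ in range(50):
            X, Y, _ = _random_problem(rng, n=24, p=6, effect=3.0)
            perm = rng.permutation(len(Y))
            vals.append(mv.cross_validated_q2(X, Y[perm], 2, 6))
        assert np.mean(vals) <= 0.0

    def test_loo_limit_equals_brute_force_oracle(self):
        """folds = n must reproduce a leave-one-out PRESS computed with an
        independent fitting implementation (sklearn)."""
        rng = np.random.default_rng(10)
        n, A = 14, 2
        x = rng.normal(size=(n, 5))
        labels = [f"g{i % 2}" for i in range(n)]
        y = np.array([float(l == "g0") for l in labels])[:, None]
        press = ss = 0.0
        for i in range(n):
            train = np.arange(n) != i
            Xs, scaler = mv.autoscale(x[train])
            y_mean = y[train].mean(axis=0)
            skl = PLSRegression(
                n_components=A, scale=False, tol=1e-12, max_iter=5000
            ).fit(Xs, y[train] - y_mean)
            y_hat = skl.predict(scaler.transform(x[i][None, :])) + y_mean
            press += float(((y[i] - y_hat) ** 2).sum())
            ss += float(((y[i] - y_mean) ** 2).sum())
        oracle = 1.0 - press / ss
        assert mv.cross_validated_q2(x, y, A, n) == pytest.approx(oracle, abs=1e-8)

    def test_fold_bounds(self):
        rng = np.random.default_rng(12)
        X, Y, _ = _random_problem(rng, n=9, p=4)
        with pytest.raises(ValidationError):
            mv.cross_validated_q2(X, Y, 1, 1)
        with pytest.raises(ValidationError):
            mv.cross_validated_q2(X, Y, 1, 10)


class TestVip:
    def test_closed_form_single_component(self):
        model = mv.fit_plsda_fixed(np.eye(4), np.eye(4)[:, :1], 1)
        model.weights = np.array([[1.0], [0.0], [0.0]])
        model.ssy = np.array([2.0])
        vip = mv.compute_vip(model)
        assert np.allclose(vip.values, [np.sqrt(3), 0.0, 0.0])

    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            X, Y, _ = _random_problem(rng, n=21, p=8)
            vip = mv.compute_vip(mv.fit_plsda_fixed(X, Y, 3))
            assert np.mean(vip.values**2) == pytest.approx(1.0, abs=1e-8)

    def test_informative_variable_has_top_vip(self):
        rng = np.random.default_rng(14)
        n = 40
        X = rng.normal(size=(n, 21))
        labels = ["a" if i < n // 2 else "b" for i in range(n)]
        X[: n // 2, 0] += 5.0
        Y = mv.one_hot(labels, ["a", "b"])
        vip = mv.compute_vip(mv.fit_plsda_fixed(X, Y, 2))
        assert vip.idxmax() == "x0" and vip["x0"] > 1.0


class TestPermutation:
    def test_identity_permutation_consistency(self):
        """Refitting with unpermuted labels reproduces R2Y and Q2 exactly."""
        rng = np.random.default_rng(15)
        X, Y, labels = _random_problem(rng, n=18, p=6)
        a = mv.fit_plsda_fixed(X, Y, 2)
        b = mv.fit_plsda_fixed(X, Y[np.arange(len(Y))], 2)
        assert a.r2y == b.r2y
        q1 = mv.cross_validated_q2(X, Y, 2, 6)
        q2 = mv.cross_validated_q2(X, Y.copy(), 2, 6)
        assert q1 == q2

    def test_report_shape_and_original_point(self):
        rng = np.random.default_rng(16)
        X, Y, labels = _random_problem(rng, n=18, p=6)
        rep = mv.permutation_test(X, labels, 2, n_permutations=10, seed=0, folds=6)
        assert rep.n_permutations == 10
        assert rep.correlations[-1] == 1.0
        assert rep.r2y[-1] == rep.original_r2y
        assert rep.q2[-1] == rep.original_q2

    def test_pure_noise_original_not_systematically_best(self):
        """With no label structure the original Q2 should rank like any
        permutation, not above all of them."""
        rng = np.random.default_rng(17)
        X = rng.normal(size=(30, 6))
        labels = [f"g{i % 3}" for i in range(30)]
        rep = mv.permutation_test(X, labels, 2, n_permutations=30, seed=1, folds=5)
        assert rep.original_q2 <= rep.q2[:-1].max()


class TestHotelling:
    def test_coverage_at_large_n(self):
        rng = np.random.default_rng(18)
        scores = rng.normal(size=(10_000, 2))
        ell = mv.hotelling_ellipse(scores, alpha=0.05)
        inside = ell.contains(scores).mean()
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(19)
        scores = rng.normal(size=(50, 2))
        e1 = mv.hotelling_ellipse(scores)
        e2 = mv.hotelling_ellipse(2.0 * scores)
        assert e2.semi_axis_1 == pytest.approx(2 * e1.semi_axis_1, rel=1e-12)
        assert e2.semi_axis_2 == pytest.approx(2 * e1.semi_axis_2, rel=1e-12)

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(20)
        scores = rng.normal(size=(40, 2))
        loose = mv.hotelling_ellipse(scores, alpha=0.05)
        tight = mv.hotelling_ellipse(scores, alpha=0.5)
        assert tight.semi_axis_1 < loose.semi_axis_1
        assert tight.semi_axis_2 < loose.semi_axis_2

    def test_minimum_points(self):
        with pytest.raises(ValidationError):
            mv.hotelling_ellipse(np.zeros((3, 2)))
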