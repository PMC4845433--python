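import numpy as np
import pytest
from scipy.optimize import minimize

from sparseppi.wsrc import (
    WSRC,
    InfeasibleEpsilonError,
    class_residuals,
    gaussian_weights,
    solve_weighted_l1,
)


def oracle_weighted_l1(X, y, w, eps):
    """Independent convex-programming solution of
    min ||W a||_1 s.t. ||y - X a|| <= eps, via the smooth split-variable
    reformulation min sum(w*(p+q)) s.t. ||y - X(p-q)||^2 <= eps^2, p,q >= 0
    solved with SLSQP."""
    m, n = X.shape
    a0, *_ = np.linalg.lstsq(X, y, rcond=None)
    z0 = np.concatenate([np.clip(a0, 0, None), np.clip(-a0, 0, None)])
    ww = np.concatenate([w, w])

    def constraint(z):
        r = y - X @ (z[:n] - z[n:])
        return eps**2 - r @ r

    def constraint_jac(z):
        r = y - X @ (z[:n] - z[n:])
        g = 2.0 * X.T @ r
        return np.concatenate([g, -g])

    starts = [
        z0,
        np.zeros(2 * n),
        z0 + 0.01 * np.abs(np.sin(np.arange(2 * n))),
    ]
    best = None
    for start in starts:
        res = minimize(
            lambda z: ww @ z, start, jac=lambda z: ww,
            bounds=[(0, None)] * (2 * n),
            constraints=[{"type": "ineq", "fun": constraint,
                          "jac": constraint_jac}],
            method="SLSQP", options={"maxiter": 1000, "ftol": 1e-14},
        )
        if constraint(res.x) >= -1e-9 * eps**2:
            obj = float(ww @ res.x)
            if best is None or obj < best[1]:
                best = (res.x, obj)
    if best is None:
        from scipy.optimize import NonlinearConstraint

        res = minimize(
            lambda z: ww @ z, z0, jac=lambda z: ww,
            bounds=[(0, None)] * (2 * n),
            constraints=[NonlinearConstraint(
                constraint, 0.0, np.inf, jac=constraint_jac)],
            method="trust-constr",
            options={"maxiter": 5000, "gtol": 1e-12, "xtol": 1e-14},
        )
        assert constraint(res.x) >= -1e-8 * eps**2, "oracle failed to converge"
        best = (res.x, float(ww @ res.x))
    z = best[0]
    alpha = z[:n] - z[n:]
    return alpha, float(np.sum(w * np.abs(alpha)))


def random_feasible_instance(rng, m_max=6, n_max=10):
    """A wide random instance (more columns than rows) so the tolerance
    constraint is satisfiable."""
    m = int(rng.integers(2, m_max + 1))
    n = int(rng.integers(m + 2, n_max + 1))
    X = rng.normal(size=(m, n))
    y = rng.normal(size=m)
    w = rng.uniform(0.3, 1.0, size=n)
    w /= w.max()
    eps = 0.2 * float(np.linalg.norm(y)) + 1e-3
    return X, y, w, eps


class TestGaussianWeights:
    def test_identical_column_gives_one(self, rng):
        X = rng.normal(size=(4, 6))
        w = gaussian_weights(X[:, 2], X, sigma=1.5)
        assert w[2] == pytest.approx(1.0)
        assert np.all((w > 0) & (w <= 1))

    def test_closed_form_at_sigma_sqrt2(self):
        sigma = 2.0
        X = np.zeros((3, 1))
        y = np.zeros(3)
        y[0] = sigma * np.sqrt(2.0)
        w = gaussian_weights(y, X, sigma)
        assert w[0] == pytest.approx(np.exp(-1.0))

    def test_large_sigma_limit(self, rng):
        X = rng.normal(size=(5, 8))
        w = gaussian_weights(rng.normal(size=5), X, sigma=1e9)
        np.testing.assert_allclose(w, 1.0, atol=1e-9)

    def test_monotone_in_distance(self, rng):
        y = np.zeros(3)
        dists = np.array([0.5, 1.0, 2.0, 4.0])
        X = np.zeros((3, 4))
        X[0, :] = dists
        w = gaussian_weights(y, X, sigma=1.5)
        assert np.all(np.diff(w) < 0)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            gaussian_weights(np.zeros(3), np.zeros((4, 2)), 1.0)

    def test_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            gaussian_weights(np.zeros(2), np.zeros((2, 2)), 0.0)


class TestSolveWeightedL1:
    def test_concentrates_on_matching_column(self, rng):
        X = rng.normal(size=(5, 8))
        j = 3
        y = X[:, j].copy()
        coef = solve_weighted_l1(X, y, np.ones(8), 1e-6, solver_tol=1e-10)
        e_j = np.zeros(8)
        e_j[j] = 1.0
        assert np.linalg.norm(coef.alpha - e_j) < 1e-3
        assert coef.feasible

    def test_oracle_equivalence_on_random_instances(self):
        """The bisection-mapped lasso path must match a generic convex
        solver's optimum on 100 small instances."""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            X, y, w, eps = random_feasible_instance(rng)
            coef = solve_weighted_l1(
                X, y, w, eps, solver_tol=1e-14, max_bisect=100
            )
            _, obj_oracle = oracle_weighted_l1(X, y, w, eps)
            worst = max(worst, abs(coef.objective - obj_oracle))
        assert worst < 1e-6

    def test_orthonormal_closed_form(self):
        """With orthonormal columns and y in the span, the optimum is the
        soft-thresholding of the coordinates, with the threshold set so the
        residual equals eps."""
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.normal(size=(8, 4)))
        c = np.array([1.5, -0.8, 0.3, 0.05])
        y = Q @ c
        eps = 0.25

        def resid_at(t):
            return np.sqrt(np.sum(np.minimum(np.abs(c), t) ** 2))

        lo, hi = 0.0, np.max(np.abs(c))
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            lo, hi = (lo, mid) if resid_at(mid) > eps else (mid, hi)
        t = 0.5 * (lo + hi)
        expected = np.sign(c) * np.maximum(np.abs(c) - t, 0.0)

        coef = solve_weighted_l1(Q, y, np.ones(4), eps, solver_tol=1e-12)
        np.testing.assert_allclose(coef.alpha, expected, atol=1e-5)

    def test_weight_substitution_identity(self, rng):
        X = rng.normal(size=(4, 9))
        y = rng.normal(size=4)
        w = rng.uniform(0.2, 1.0, size=9)
        w /= w.max()
        eps = 0.3 * np.linalg.norm(y)
        a = solve_weighted_l1(X, y, w, eps, solver_tol=1e-10)
        b = solve_weighted_l1(X / w, y, np.ones(9), eps, solver_tol=1e-10)
        assert a.objective == pytest.approx(b.objective, abs=1e-6)
        np.testing.assert_allclose(a.alpha, b.alpha / w, atol=1e-5)

    def test_feasibility_of_returned_solution(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            X, y, w, eps = random_feasible_instance(rng)
            coef = solve_weighted_l1(X, y, w, eps, solver_tol=1e-10)
            assert np.linalg.norm(y - X @ coef.alpha) <= eps + 1e-6

    def test_trivially_feasible_zero(self, rng):
        X = rng.normal(size=(4, 6))
        y = 1e-8 * np.ones(4)
        coef = solve_weighted_l1(X, y, np.ones(6), eps := 1e-3)
        assert np.all(coef.alpha == 0)
        assert coef.feasible

    def test_infeasible_raises(self, rng):
        X = rng.normal(size=(10, 3))  # tall: y generically outside the span
        y = rng.normal(size=10)
        with pytest.raises(InfeasibleEpsilonError):
            solve_weighted_l1(X, y, np.ones(3), 1e-8)

    def test_infeasible_fallback_warns(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        with pytest.warns(UserWarning, match="infeasible"):
            coef = solve_weighted_l1(
                X, y, np.ones(3), 1e-8, on_infeasible="fallback"
            )
        assert coef.fallback and not coef.feasible

    def test_invalid_epsilon(self, rng):
        with pytest.raises(ValueError):
            solve_weighted_l1(np.eye(2), np.ones(2), np.ones(2), 0.0)


class TestClassResiduals:
    def test_zero_alpha_gives_y_norm(self, rng):
        X = rng.normal(size=(5, 6))
        labels = np.array([0, 0, 0, 1, 1, 1])
        y = rng.normal(size=5)
        r = class_residuals(X, labels, np.zeros(6), y)
        assert r[0] == pytest.approx(np.linalg.norm(y))
        assert r[1] == pytest.approx(np.linalg.norm(y))

    def test_exact_single_class_reconstruction(self, rng):
        X = rng.normal(size=(5, 6))
        labels = np.array([0, 0, 0, 1, 1, 1])
        alpha = np.array([0.5, -1.0, 0.2, 0.0, 0.0, 0.0])
        y = X @ alpha
        r = class_residuals(X, labels, alpha, y)
        assert r[0] == pytest.approx(0.0, abs=1e-12)
        assert r[1] == pytest.approx(np.linalg.norm(y))

    def test_permutation_within_class_invariant(self, rng):
        X = rng.normal(size=(5, 6))
        labels = np.array([0, 0, 0, 1, 1, 1])
        alpha = rng.normal(size=6)
        y = rng.normal(size=5)
        r1 = class_residuals(X, labels, alpha, y)
        perm = [2, 0, 1, 5, 3, 4]  # permutes within each class block
        r2 = class_residuals(X[:, perm], labels[perm], alpha[perm], y)
        for c in (0, 1):
            assert r1[c] == pytest.approx(r2[c], abs=1e-10)

    def test_residual_decomposition(self, rng):
        X = rng.normal(size=(5, 8))
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        alpha = rng.normal(size=8)
        total = np.zeros(5)
        for c in (0, 1):
            d = np.where(labels == c, alpha, 0.0)
            total += X @ d
        np.testing.assert_allclose(total, X @ alpha, atol=1e-12)


def two_cluster_data(rng, n_train=50, n_test=20, dim=20, separation=10.0):
    centers = {0: np.zeros(dim), 1: np.full(dim, separation / np.sqrt(dim))}
    Xtr, ytr, Xte, yte = [], [], [], []
    for c, mu in centers.items():
        Xtr.append(mu + rng.normal(size=(n_train, dim)))
        ytr.extend([c] * n_train)
        Xte.append(mu + rng.normal(size=(n_test, dim)))
        yte.extend([c] * n_test)
    return (np.vstack(Xtr), np.array(ytr), np.vstack(Xte), np.array(yte))


class TestWSRCPredict:
    def test_separated_clusters_perfect_accuracy(self, rng):
        Xtr, ytr, Xte, yte = two_cluster_data(rng)
        model = WSRC().fit(Xtr, ytr)
        assert np.array_equal(model.predict(Xte), yte)

    def test_training_sample_recovers_own_class(self, rng):
        Xtr, ytr, _, _ = two_cluster_data(rng, n_train=20, n_test=1)
        model = WSRC().fit(Xtr, ytr)
        for i in (0, 25):
            assert model.predict_one(Xtr[i]).predicted_class == ytr[i]

    def test_tie_breaks_to_lowest_class(self, rng):
        Xtr = rng.normal(size=(8, 5))
        ytr = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        model = WSRC().fit(Xtr, ytr)
        res = model.predict_one(np.zeros(5))  # alpha = 0, all residuals 0
        assert res.predicted_class == 0

    def test_score_sign_consistent_with_prediction(self, rng):
        Xtr, ytr, Xte, _ = two_cluster_data(rng, n_train=15, n_test=5)
        model = WSRC().fit(Xtr, ytr)
        for r in model.predict_batch(Xte):
            if r.score > 0:
                assert r.predicted_class == 1

    def test_batch_consistency_and_order(self, rng):
        Xtr, ytr, Xte, _ = two_cluster_data(rng, n_train=15, n_test=4)
        model = WSRC().fit(Xtr, ytr)
        batch = model.predict_batch(Xte)
        single = [model.predict_one(row) for row in Xte]
        assert [r.predicted_class for r in batch] == [
            r.predicted_class for r in single
        ]
        perm = [3, 1, 0, 2, 7, 5, 4, 6]
        permuted = model.predict_batch(Xte[perm])
        assert [r.predicted_class for r in permuted] == [
            batch[i].predicted_class for i in perm
        ]

    def test_empty_batch(self, rng):
        Xtr, ytr, _, _ = two_cluster_data(rng, n_train=10, n_test=1)
        model = WSRC().fit(Xtr, ytr)
        assert model.predict_batch(np.empty((0, 20))) == []

    def test_minimum_residual_rule(self, rng):
        Xtr, ytr, Xte, _ = two_cluster_data(rng, n_train=15, n_test=5)
        model = WSRC().fit(Xtr, ytr)
        for r in model.predict_batch(Xte):
            assert r.predicted_class == min(
                r.residuals, key=lambda c: (r.residuals[c], c)
            )
            assert all(v >= 0 for v in r.residuals.values())

    def test_single_class_training_rejected(self, rng):
        with pytest.raises(ValueError):
            WSRC().fit(rng.normal(size=(5, 3)), np.zeros(5, dtype=int))

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError):
            WSRC().predict(np.zeros((1, 3)))

    def test_locality_mode_classifies_clusters(self, rng):
        Xtr, ytr, Xte, yte = two_cluster_data(rng, n_train=15, n_test=5)
        model = WSRC(weight_mode="inverse_similarity").fit(Xtr, ytr)
        assert (model.predict(Xte) == yte).mean() >= 0.9

    def test_literal_similarity_mode_runs(self, rng):
        # The literal weighting rule penalizes near samples more, so no
        # accuracy is promised here — only a valid, deterministic output.
        Xtr, ytr, Xte, _ = two_cluster_data(rng, n_train=15, n_test=5)
        model = WSRC(weight_mode="similarity").fit(Xtr, ytr)
        preds = model.predict(Xte)
        assert set(preds) <= {0, 1}
        np.testing.assert_array_equal(preds, model.predict(Xte))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        Xtr, ytr, Xte, _ = two_cluster_data(rng, n_train=12, n_test=6)
        model = WSRC(sigma=2.5, epsilon=1e-4, penalty=5e-3).fit(Xtr, ytr)
        model.save(tmp_path / "model")
        loaded = WSRC.load(tmp_path / "model")
        assert loaded.sigma == 2.5 and loaded.penalty == 5e-3
        np.testing.assert_array_equal(model.predict(Xte), loaded.predict(Xte))


class TestPlantedSignalRecovery:
    def test_accuracy_on_planted_signal(self, small_dataset):
        """High accuracy when the class composition shift is large."""
        from sparseppi.encoding import GlobalEncoder

        proteins, pairs = small_dataset
        X, y = GlobalEncoder().encode_pairs(pairs, proteins)
        rng = np.random.default_rng(3)
        idx = rng.permutation(len(y))
        tr, te = idx[:40], idx[40:]
        model = WSRC().fit(X[tr], y[tr])
        acc = (model.predict(X[te]) == y[te]).mean()
        assert acc >= 0.9
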