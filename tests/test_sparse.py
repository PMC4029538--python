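"""SRC core: dictionary assembly, l1 solver vs convex oracle, residuals."""

import numpy as np
import pytest
from scipy.optimize import minimize

from mammosrc import (Dictionary, SolverConfig, ValidationError,
                      build_dictionary, class_residual, classify_single,
                      sparse_code)


def lasso_oracle(A, y, lam):
    """High-accuracy solve of 0.5||Ax-y||^2 + lam||x||_1 via the
    nonnegative split x = p - q and bound-constrained quasi-Newton."""
    n = A.shape[1]

    def f(z):
        x = z[:n] - z[n:]
        return 0.5 * np.sum((A @ x - y) ** 2) + lam * z.sum()

    def grad(z):
        x = z[:n] - z[n:]
        g = A.T @ (A @ x - y)
        return np.concatenate([g + lam, -g + lam])

    res = minimize(f, np.zeros(2 * n), jac=grad, bounds=[(0, None)] * 2 * n,
                   method="L-BFGS-B",
                   options=dict(ftol=1e-16, gtol=1e-12, maxiter=10000))
    return res.fun


def random_dictionary(rng, d, n):
    X = rng.standard_normal((n, d))
    labels = np.array(["mass"] * (n // 2) + ["normal"] * (n - n // 2),
                      dtype=object)
    return build_dictionary(X, labels)


class TestBuildDictionary:
    def test_assembly_shapes_and_order(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 10))
        labels = np.array(["normal"] * 5 + ["mass"] * 3, dtype=object)
        D = build_dictionary(X, labels)
        assert D.atoms.shape == (10, 8)
        assert list(D.atom_class) == ["mass"] * 3 + ["normal"] * 5
        assert D.n_per_class() == {"mass": 3, "normal": 5}

    def test_columns_unit_norm(self):
        rng = np.random.default_rng(1)
        D = random_dictionary(rng, 6, 9)
        np.testing.assert_allclose(np.linalg.norm(D.atoms, axis=0), 1.0,
                                   atol=1e-12)

    def test_duplicate_samples_kept(self):
        X = np.vstack([np.ones(4), np.ones(4), np.zeros(4)])
        labels = np.array(["mass", "mass", "normal"], dtype=object)
        D = build_dictionary(X, labels)
        np.testing.assert_allclose(D.atoms[:, 0], D.atoms[:, 1])

    def test_empty_class_rejected(self):
        X = np.ones((3, 4))
        labels = np.array(["mass"] * 3, dtype=object)
        with pytest.raises(ValidationError, match="normal"):
            build_dictionary(X, labels)


class TestSparseCode:
    def test_atom_of_orthogonal_dictionary_recovers_support(self):
        atoms = np.eye(4)
        D = Dictionary(atoms, np.array(["mass", "mass", "normal", "normal"],
                                       dtype=object))
        y = atoms[:, 1].copy()
        sol = sparse_code(D, y, SolverConfig(lam=0.01))
        assert np.flatnonzero(np.abs(sol.coefficients) > 1e-9).tolist() == [1]
        # soft-threshold shrinkage bound: residual <= lam
        assert sol.residual_norm <= 0.01 + 1e-9

    def test_zero_input_gives_zero_code(self):
        rng = np.random.default_rng(2)
        D = random_dictionary(rng, 5, 8)
        sol = sparse_code(D, np.zeros(5))
        np.testing.assert_array_equal(sol.coefficients, 0.0)
        assert sol.residual_norm == 0.0

    def test_objective_matches_convex_oracle_small_instance(self):
        rng = np.random.default_rng(3)
        D = random_dictionary(rng, 3, 4)
        y = rng.standard_normal(3)
        lam = 0.05
        sol = sparse_code(D, y, SolverConfig(lam=lam, max_iter=5000,
                                             tol=1e-12))
        obj = (0.5 * np.sum((D.atoms @ sol.coefficients - y) ** 2)
               + lam * np.abs(sol.coefficients).sum())
        assert obj == pytest.approx(lasso_oracle(D.atoms, y, lam), abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        D = random_dictionary(rng, 5, 8)
        with pytest.raises(ValidationError, match="y"):
            sparse_code(D, np.zeros(4))

    def test_sparsity_grows_with_lambda(self):
        """Support size is non-increasing on average as lam grows."""
        rng = np.random.default_rng(6)
        sizes = {0.01: [], 0.3: []}
        for _ in range(10):
            D = random_dictionary(rng, 8, 16)
            y = rng.standard_normal(8)
            for lam in sizes:
                sol = sparse_code(D, y, SolverConfig(lam=lam))
                sizes[lam].append(
                    np.count_nonzero(np.abs(sol.coefficients) > 1e-10))
        assert np.mean(sizes[0.3]) <= np.mean(sizes[0.01])


class TestClassResidual:
    def test_perfect_fit_with_mass_atoms(self):
        atoms = np.eye(3)
        D = Dictionary(atoms, np.array(["mass", "mass", "normal"],
                                       dtype=object))
        y = np.array([2.0, -1.0, 0.0])
        sol = sparse_code(D, y, SolverConfig(lam=1e-10, max_iter=5000))
        assert class_residual(D, y, sol, "mass") < 1e-6

    def test_empty_selection_returns_input_norm(self):
        rng = np.random.default_rng(7)
        D = random_dictionary(rng, 4, 6)
        y = rng.standard_normal(4)
        sol = sparse_code(D, y)
        sol.coefficients[:] = 0.0
        sol.coefficients[np.asarray(D.atom_class) == "mass"] = 0.3
        assert class_residual(D, y, sol, "normal") == pytest.approx(
            np.linalg.norm(y))

    def test_two_class_toy_matches_hand_computation(self):
        atoms = np.array([[1.0, 0.0, 0.0],
                          [0.0, 1.0, 0.0],
                          [0.0, 0.0, 1.0]])
        D = Dictionary(atoms, np.array(["mass", "normal", "normal"],
                                       dtype=object))
        y = np.array([1.0, 2.0, 3.0])
        sol = sparse_code(D, y, SolverConfig(lam=1e-8, max_iter=5000))
        x = sol.coefficients
        r_mass_hand = np.linalg.norm(y - atoms @ (x * [1, 0, 0]))
        r_norm_hand = np.linalg.norm(y - atoms @ (x * [0, 1, 1]))
        assert class_residual(D, y, sol, "mass") == pytest.approx(r_mass_hand)
        assert class_residual(D, y, sol, "normal") == pytest.approx(
            r_norm_hand)

    def test_residual_bounds_property(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            D = random_dictionary(rng, 6, 10)
            y = rng.standard_normal(6)
            sol = sparse_code(D, y)
            for cls in ("mass", "normal"):
                r = class_residual(D, y, sol, cls)
                x = np.where(D.class_mask(cls), sol.coefficients, 0.0)
                assert 0 <= r <= np.linalg.norm(y) + np.linalg.norm(
                    D.atoms @ x) + 1e-12


class TestClassifySingle:
    def test_well_separated_clusters_match_subspace_oracle(self):
        """Agreement with a nearest-class-least-squares oracle.

        The classes are separated both in mean and in low-rank covariance
        orientation.  The structural separation matters: after the
        dictionary's centering, coding is sign-agnostic, so a purely
        symmetric mean offset would lie in both class spans and carry no
        least-squares signal.
        """
        rng = np.random.default_rng(9)
        d, rank, n_train, gap = 30, 5, 15, 5.0
        u = rng.standard_normal(d)
        u /= np.linalg.norm(u)
        Bm, _ = np.linalg.qr(rng.standard_normal((d, rank)))
        Bn, _ = np.linalg.qr(rng.standard_normal((d, rank)))

        def draw(n, mean, B):
            return (mean + (3.0 * rng.standard_normal((n, rank))) @ B.T
                    + 0.3 * rng.standard_normal((n, d)))

        Xm = draw(n_train, gap * u, Bm)
        Xn = draw(n_train, np.zeros(d), Bn)
        X = np.vstack([Xm, Xn])
        labels = np.array(["mass"] * n_train + ["normal"] * n_train,
                          dtype=object)
        D = build_dictionary(X, labels)
        test = np.vstack([draw(25, gap * u, Bm), draw(25, np.zeros(d), Bn)])
        truth = ["mass"] * 25 + ["normal"] * 25

        def oracle(y):
            yt = D.transform(y)
            res = {}
            for cls in ("mass", "normal"):
                A = D.atoms[:, D.class_mask(cls)]
                coef, *_ = np.linalg.lstsq(A, yt, rcond=None)
                res[cls] = np.linalg.norm(yt - A @ coef)
            return "mass" if res["mass"] < res["normal"] else "normal"

        agree = correct = 0
        for y, t in zip(test, truth):
            pred = classify_single(D, y)
            agree += pred == oracle(y)
            correct += pred == t
        assert agree == 50
        assert correct == 50

    def test_tie_goes_to_normal(self):
        atoms = np.eye(2)
        D = Dictionary(atoms, np.array(["mass", "normal"], dtype=object))
        # y symmetric between the two atoms -> exactly equal residuals
        assert classify_single(D, np.array([1.0, 1.0]),
                               SolverConfig(lam=0.01)) == "normal"
        # zero vector: both residuals zero, also a tie
        assert classify_single(D, np.zeros(2)) == "normal"
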