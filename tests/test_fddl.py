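"""FDDL: objective formula oracle, monotone learning, discriminative gain."""

import numpy as np
import pytest

from mammosrc import FDDLParams, ValidationError, fddl_learn, fddl_objective
from mammosrc.sparse import Dictionary, SolverConfig, class_residual, sparse_code


def reference_objective(D, X, data, p):
    """Straight-from-definition recomputation of the FDDL objective."""
    classes = ("mass", "normal")
    m = {c: D[c].shape[1] for c in classes}
    rows = {"mass": slice(0, m["mass"]),
            "normal": slice(m["mass"], m["mass"] + m["normal"])}
    Dfull = np.hstack([D["mass"], D["normal"]])
    total = 0.0
    for i in classes:
        Ai, Xi = data[i], X[i]
        total += np.sum((Ai - Dfull @ Xi) ** 2)
        total += np.sum((Ai - D[i] @ Xi[rows[i]]) ** 2)
        for j in classes:
            if j != i:
                total += np.sum((D[j] @ Xi[rows[j]]) ** 2)
        total += p.lambda1 * np.abs(Xi).sum()
    allX = np.hstack([X[c] for c in classes])
    gm = allX.mean(axis=1, keepdims=True)
    sw = sb = 0.0
    for c in classes:
        mc = X[c].mean(axis=1, keepdims=True)
        sw += np.sum((X[c] - mc) ** 2)
        sb += X[c].shape[1] * np.sum((mc - gm) ** 2)
    total += p.lambda2 * (sw - sb + p.eta * np.sum(allX ** 2))
    return total


def random_instance(seed, d=6, n=10, m=4):
    rng = np.random.default_rng(seed)
    data = {"mass": rng.standard_normal((d, n)) + 1.5,
            "normal": rng.standard_normal((d, n))}
    D = {}
    for c in data:
        atoms = rng.standard_normal((d, m))
        D[c] = atoms / np.linalg.norm(atoms, axis=0)
    X = {c: rng.standard_normal((2 * m, n)) * 0.3 for c in data}
    return D, X, data


class TestObjective:
    def test_zero_codes_closed_form(self):
        D, X, data = random_instance(0)
        X0 = {c: np.zeros_like(X[c]) for c in X}
        p = FDDLParams(lambda1=0.0, lambda2=0.0)
        expected = 2 * sum(np.sum(data[c] ** 2) for c in data)
        assert fddl_objective(D, X0, data, p) == pytest.approx(expected)

    def test_block_structured_codes_have_no_cross_penalty(self):
        """Data in its own sub-dictionary span with zero cross-class codes
        leaves only the l1/Fisher terms."""
        rng = np.random.default_rng(1)
        d, m, n = 5, 3, 4
        D = {}
        for c in ("mass", "normal"):
            atoms = rng.standard_normal((d, m))
            D[c] = atoms / np.linalg.norm(atoms, axis=0)
        codes = {"mass": rng.standard_normal((m, n)),
                 "normal": rng.standard_normal((m, n))}
        data = {c: D[c] @ codes[c] for c in D}
        X = {"mass": np.vstack([codes["mass"], np.zeros((m, n))]),
             "normal": np.vstack([np.zeros((m, n)), codes["normal"]])}
        p = FDDLParams(lambda1=0.0, lambda2=0.0)
        assert fddl_objective(D, X, data, p) == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_definition_oracle(self, seed):
        D, X, data = random_instance(seed)
        p = FDDLParams(lambda1=0.07, lambda2=0.03, eta=0.5)
        assert fddl_objective(D, X, data, p) == pytest.approx(
            reference_objective(D, X, data, p), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        D, X, data = random_instance(2)
        X["mass"] = X["mass"][:, :-1]
        with pytest.raises(ValidationError):
            fddl_objective(D, X, data, FDDLParams())


class TestLearning:
    @pytest.mark.parametrize("seed", range(6))
    def test_objective_trace_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        data = {"mass": rng.standard_normal((6, 12)) + 1.0,
                "normal": rng.standard_normal((6, 12))}
        ld = fddl_learn(data, FDDLParams(atoms_per_class=4, max_iter=8),
                        seed=seed)
        tr = np.asarray(ld.objective_trace)
        assert np.all(np.diff(tr) <= 1e-8 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_atoms_unit_norm(self):
        rng = np.random.default_rng(3)
        data = {"mass": rng.standard_normal((5, 10)) + 1.0,
                "normal": rng.standard_normal((5, 10))}
        ld = fddl_learn(data, FDDLParams(atoms_per_class=3, max_iter=5),
                        seed=0)
        np.testing.assert_allclose(
            np.linalg.norm(ld.dictionary.atoms, axis=0), 1.0, atol=1e-12)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        data = {"mass": rng.standard_normal((5, 10)) + 1.0,
                "normal": rng.standard_normal((5, 10))}
        a = fddl_learn(data, FDDLParams(atoms_per_class=3, max_iter=3),
                       seed=11)
        b = fddl_learn(data, FDDLParams(atoms_per_class=3, max_iter=3),
                       seed=11)
        np.testing.assert_array_equal(a.dictionary.atoms, b.dictionary.atoms)

    def test_lambda2_zero_still_monotone(self):
        rng = np.random.default_rng(5)
        data = {"mass": rng.standard_normal((6, 10)) + 1.0,
                "normal": rng.standard_normal((6, 10))}
        ld = fddl_learn(data, FDDLParams(atoms_per_class=4, lambda2=0.0,
                                         max_iter=6), seed=0)
        tr = np.asarray(ld.objective_trace)
        assert np.all(np.diff(tr) <= 1e-8 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError, match="normal"):
            fddl_learn({"mass": np.ones((3, 4)),
                        "normal": np.empty((3, 0))})

    def test_undersampled_class_warns(self):
        rng = np.random.default_rng(6)
        data = {"mass": rng.standard_normal((4, 2)),
                "normal": rng.standard_normal((4, 8))}
        with pytest.warns(UserWarning, match="mass"):
            fddl_learn(data, FDDLParams(atoms_per_class=4, max_iter=2),
                       seed=0)

    def test_learned_beats_random_sample_dictionary(self):
        """Learned atoms classify at least as well as raw sampled atoms,
        averaged over paired seeds, on two separated Gaussian classes."""

        def accuracy(dictionary, test_X, test_labels):
            good = 0
            for y, t in zip(test_X, test_labels):
                sol = sparse_code(dictionary, y, SolverConfig())
                rm = class_residual(dictionary, y, sol, "mass")
                rn = class_residual(dictionary, y, sol, "normal")
                good += ("mass" if rm < rn else "normal") == t
            return good / len(test_labels)

        gains = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            d, n, m_i = 8, 15, 5
            mu = rng.standard_normal(d)
            mu *= 4.0 / np.linalg.norm(mu)
            train = {"mass": rng.standard_normal((d, n)) + mu[:, None],
                     "normal": rng.standard_normal((d, n))}
            test_X = np.vstack([rng.standard_normal((10, d)) + mu,
                                rng.standard_normal((10, d))])
            test_labels = ["mass"] * 10 + ["normal"] * 10

            ld = fddl_learn(train, FDDLParams(atoms_per_class=m_i,
                                              max_iter=10), seed=seed)
            idx = np.random.default_rng(seed).choice(n, m_i, replace=False)
            raw = np.hstack([train["mass"][:, idx], train["normal"][:, idx]])
            raw = raw / np.linalg.norm(raw, axis=0)
            labels = np.array(["mass"] * m_i + ["normal"] * m_i,
                              dtype=object)
            raw_dict = Dictionary(raw, labels)
            gains.append(accuracy(ld.dictionary, test_X, test_labels)
                         - accuracy(raw_dict, test_X, test_labels))
        assert np.mean(gains) >= 0.0
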