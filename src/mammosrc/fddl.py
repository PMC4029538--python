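"""Fisher discrimination dictionary learning (FDDL).

Learns a class-structured dictionary ``D = [D_mass, D_normal]`` from
per-class training matrices ``A_i`` by minimizing

    sum_i { ||A_i - D X_i||_F^2 + ||A_i - D_i X_i^i||_F^2
            + sum_{j != i} ||D_j X_i^j||_F^2 }
    + lambda1 ||X||_1
    + lambda2 ( tr S_W(X) - tr S_B(X) + eta ||X||_F^2 ),

where ``X_i`` are the codes of class ``i``'s samples, ``X_i^j`` the rows
belonging to sub-dictionary ``j``, and ``S_W``/``S_B`` the within- and
between-class scatter of the coding coefficients.  The first group of terms
makes each sub-dictionary reconstruct its own class and penalizes
cross-class representation; the Fisher term pulls same-class codes together
and pushes class code means apart, with the elastic ``eta ||X||^2`` keeping
the term well behaved.

Optimization alternates class-wise proximal-gradient coding (X update, with
the dictionary fixed) and closed-form atom-by-atom dictionary updates under
the unit-norm constraint (D update, with the codes fixed).  Both steps are
monotone: the coding step uses a majorizing step size plus an explicit
accept/reject safeguard, and each atom update is the exact constrained
minimizer given all other variables, so the recorded objective trace is
non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .roi import ValidationError
from .sparse import CLASS_ORDER, Dictionary


@dataclass(frozen=True)
class FDDLParams:
    """FDDL hyperparameters.

    ``atoms_per_class`` of ``None`` means ``min(n_i, 40)`` per class.
    """

    atoms_per_class: int | None = None
    lambda1: float = 0.01
    lambda2: float = 0.01
    eta: float = 1.0
    max_iter: int = 15
    tol: float = 1e-4
    coding_iter: int = 50

    def __post_init__(self) -> None:
        if self.atoms_per_class is not None and self.atoms_per_class < 1:
            raise ValidationError("atoms_per_class: must be >= 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValidationError("lambda1/lambda2: must be >= 0")
        if self.eta <= 0:
            raise ValidationError("eta: must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter: must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol: must be > 0")


@dataclass
class LearnedDictionary:
    """A learned two-class dictionary plus its training record."""

    dictionary: Dictionary
    params: FDDLParams
    objective_trace: list[float] = field(default_factory=list)

    @property
    def final_objective(self) -> float:
        return self.objective_trace[-1] if self.objective_trace else np.nan


def _class_rows(m_per_class: dict[str, int]) -> dict[str, slice]:
    rows, off = {}, 0
    for c in CLASS_ORDER:
        rows[c] = slice(off, off + m_per_class[c])
        off += m_per_class[c]
    return rows


def _scatter_terms(X: dict[str, np.ndarray]) -> float:
    """tr S_W - tr S_B over the coding coefficients (columns are samples)."""
    cols = [X[c] for c in CLASS_ORDER if X[c].shape[1] > 0]
    all_X = np.hstack(cols)
    gmean = all_X.mean(axis=1, keepdims=True)
    sw = sb = 0.0
    for c in CLASS_ORDER:
        Xc = X[c]
        if Xc.shape[1] == 0:
            continue
        mc = Xc.mean(axis=1, keepdims=True)
        sw += float(((Xc - mc) ** 2).sum())
        sb += Xc.shape[1] * float(((mc - gmean) ** 2).sum())
    return sw - sb


def fddl_objective(D: dict[str, np.ndarray], X: dict[str, np.ndarray],
                   data: dict[str, np.ndarray], params: FDDLParams) -> float:
    """Evaluate the full FDDL objective (see module docstring)."""
    m_per_class = {c: D[c].shape[1] for c in CLASS_ORDER}
    rows = _class_rows(m_per_class)
    Dfull = np.hstack([D[c] for c in CLASS_ORDER])
    total = 0.0
    for i in CLASS_ORDER:
        Ai, Xi = data[i], X[i]
        if Ai.shape[1] != Xi.shape[1]:
            raise ValidationError("codes: sample count mismatch")
        if Xi.shape[0] != Dfull.shape[1]:
            raise ValidationError("codes: row count must equal atom count")
        total += float(((Ai - Dfull @ Xi) ** 2).sum())
        total += float(((Ai - D[i] @ Xi[rows[i]]) ** 2).sum())
        for j in CLASS_ORDER:
            if j != i:
                total += float(((D[j] @ Xi[rows[j]]) ** 2).sum())
    l1 = sum(float(np.abs(X[c]).sum()) for c in CLASS_ORDER)
    fro2 = sum(float((X[c] ** 2).sum()) for c in CLASS_ORDER)
    total += params.lambda1 * l1
    total += params.lambda2 * (_scatter_terms(X) + params.eta * fro2)
    return total


def _code_class(i: str, D: dict[str, np.ndarray], X: dict[str, np.ndarray],
                data: dict[str, np.ndarray], params: FDDLParams) -> None:
    """Proximal-gradient update of X_i with everything else fixed.

    The step size majorizes the smooth part's curvature, so each inner
    iteration cannot increase the objective; an explicit objective check
    guards against numerical slip.
    """
    m_per_class = {c: D[c].shape[1] for c in CLASS_ORDER}
    rows = _class_rows(m_per_class)
    Dfull = np.hstack([D[c] for c in CLASS_ORDER])
    Ai = data[i]
    n_i = Ai.shape[1]
    if n_i == 0:
        return
    others = [c for c in CLASS_ORDER if c != i and data[c].shape[1] > 0]
    n_total = n_i + sum(data[c].shape[1] for c in others)
    # Mean of the other classes' codes contributes to the global code mean.
    other_sum = sum(X[c].sum(axis=1) for c in others) if others else 0.0

    # Lipschitz bound for the smooth gradient: fidelity blocks + Fisher.
    L_fid = 2.0 * (np.linalg.norm(Dfull, 2) ** 2
                   + max(np.linalg.norm(D[c], 2) ** 2 for c in CLASS_ORDER))
    L_fisher = 2.0 * params.lambda2 * (4.0 + params.eta)
    step = 1.0 / (L_fid + L_fisher + 1e-12)

    # Fold the shared and block-diagonal fidelity terms into one quadratic:
    # smooth fidelity gradient = 2 (Q Xi - b).
    Q = Dfull.T @ Dfull
    for j in CLASS_ORDER:
        Q[rows[j], rows[j]] += D[j].T @ D[j]
    b = Dfull.T @ Ai
    b[rows[i]] += D[i].T @ Ai

    def smooth_grad(Xi: np.ndarray) -> np.ndarray:
        g = 2.0 * (Q @ Xi - b)
        if params.lambda2 > 0:
            mi = Xi.mean(axis=1, keepdims=True)
            gmean = ((Xi.sum(axis=1) + other_sum) / n_total)[:, None]
            g += 2.0 * params.lambda2 * ((Xi - mi) - (mi - gmean)
                                         + params.eta * Xi)
        return g

    before = fddl_objective(D, X, data, params)
    Xi = X[i].copy()
    thr = step * params.lambda1
    for _ in range(params.coding_iter):
        g = smooth_grad(Xi)
        Xi_new = Xi - step * g
        Xi_new = np.sign(Xi_new) * np.maximum(np.abs(Xi_new) - thr, 0.0)
        delta = np.abs(Xi_new - Xi).max()
        Xi = Xi_new
        if delta <= 1e-6 * max(1.0, np.abs(Xi).max()):
            break
    trial = dict(X)
    trial[i] = Xi
    after = fddl_objective(D, trial, data, params)
    if after <= before:
        X[i] = Xi


def _update_dictionary(D: dict[str, np.ndarray], X: dict[str, np.ndarray],
                       data: dict[str, np.ndarray]) -> None:
    """Exact atom-by-atom update under the unit-norm constraint.

    For each atom, every quadratic term it appears in has the form
    ``||E - d c^T||_F^2`` with ``E`` the residual excluding that atom and
    ``c`` the atom's coefficient row; the constrained minimizer is
    ``d = v / ||v||`` with ``v = sum_terms E c``.
    """
    m_per_class = {c: D[c].shape[1] for c in CLASS_ORDER}
    rows = _class_rows(m_per_class)
    Dfull = np.hstack([D[c] for c in CLASS_ORDER])
    # Cached residuals, updated rank-1 as atoms change:
    #   R[j]       = A_j - D X_j            (shared fidelity)
    #   R_own[i]   = A_i - D_i X_i^i        (own-class fidelity)
    #   C[(i, j)]  = D_i X_j^i, j != i      (cross-class penalty)
    R = {j: data[j] - Dfull @ X[j] for j in CLASS_ORDER}
    R_own = {ii: data[ii] - D[ii] @ X[ii][rows[ii]] for ii in CLASS_ORDER}
    C = {(ii, j): D[ii] @ X[j][rows[ii]]
         for ii in CLASS_ORDER for j in CLASS_ORDER if j != ii}
    for i in CLASS_ORDER:
        base = rows[i].start
        for k in range(m_per_class[i]):
            gk = base + k  # global atom index
            dk = D[i][:, k].copy()
            v = np.zeros(D[i].shape[0])
            for j in CLASS_ORDER:
                Xj = X[j]
                if Xj.shape[1] == 0:
                    continue
                c_row = Xj[gk]
                v += R[j] @ c_row + dk * (c_row @ c_row)
                c_local = Xj[rows[i]][k]
                if j == i:
                    v += R_own[i] @ c_local + dk * (c_local @ c_local)
                else:
                    v += -(C[(i, j)] @ c_local) + dk * (c_local @ c_local)
            nv = np.linalg.norm(v)
            if nv == 0:
                continue
            dk_new = v / nv
            diff = dk - dk_new
            for j in CLASS_ORDER:
                if X[j].shape[1] == 0:
                    continue
                R[j] += np.outer(diff, X[j][gk])
                if j == i:
                    R_own[i] += np.outer(diff, X[i][rows[i]][k])
                else:
                    C[(i, j)] -= np.outer(diff, X[j][rows[i]][k])
            D[i][:, k] = dk_new


def fddl_learn(data: dict[str, np.ndarray], params: FDDLParams | None = None,
               seed: int = 0) -> LearnedDictionary:
    """Learn a two-class dictionary from per-class d x n_i sample matrices.

    Atoms are initialized from a seeded sample of each class's own columns
    (normalized); learning alternates coding and dictionary updates until
    the relative objective change falls below ``params.tol``.
    """
    params = params or FDDLParams()
    for c in CLASS_ORDER:
        if c not in data or data[c].size == 0:
            raise ValidationError(f"data: class {c!r} is empty")
    data = {c: np.asarray(data[c], dtype=float) for c in CLASS_ORDER}
    d = data[CLASS_ORDER[0]].shape[0]
    rng = np.random.default_rng(seed)

    D: dict[str, np.ndarray] = {}
    for c in CLASS_ORDER:
        n_c = data[c].shape[1]
        m_c = params.atoms_per_class or min(n_c, 40)
        if n_c < m_c:
            warnings.warn(
                f"class {c!r}: only {n_c} samples for {m_c} atoms; "
                "sampling with replacement", stacklevel=2)
            idx = rng.choice(n_c, size=m_c, replace=True)
        else:
            idx = rng.choice(n_c, size=m_c, replace=False)
        atoms = data[c][:, np.sort(idx)].copy()
        atoms += 1e-8 * rng.standard_normal(atoms.shape)  # break exact ties
        norms = np.linalg.norm(atoms, axis=0)
        D[c] = atoms / np.where(norms > 0, norms, 1.0)

    m_total = sum(D[c].shape[1] for c in CLASS_ORDER)
    X = {c: np.zeros((m_total, data[c].shape[1])) for c in CLASS_ORDER}

    trace = [fddl_objective(D, X, data, params)]
    for _ in range(params.max_iter):
        for c in CLASS_ORDER:
            _code_class(c, D, X, data, params)
        _update_dictionary(D, X, data)
        obj = fddl_objective(D, X, data, params)
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= params.tol * max(abs(prev), 1e-12):
            break

    atoms = np.hstack([D[c] for c in CLASS_ORDER])
    atom_class = np.concatenate(
        [np.full(D[c].shape[1], c, dtype=object) for c in CLASS_ORDER])
    dictionary = Dictionary(atoms, atom_class)
    return LearnedDictionary(dictionary, params, trace)
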