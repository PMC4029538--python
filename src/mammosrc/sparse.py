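"""Sparse representation classification with a single two-class dictionary.

Training feature vectors are stacked as unit-norm dictionary atoms, the
mass-class block first.  A test vector ``y`` is sparse-coded against the
dictionary by solving the lasso-form problem

    minimize  0.5 * ||A x - y||_2^2  +  lambda * ||x||_1

with an accelerated proximal-gradient (FISTA) iteration, and is assigned to
the class whose atoms reconstruct it with the smaller residual
``r_i(y) = ||y - A delta_i(x)||_2``, where ``delta_i`` zeroes the
coefficients outside class ``i``.  The epsilon-constrained basis-pursuit
form of the coding problem is equivalent to this Lagrangian form for a
matching multiplier; the multiplier defaults to ``0.01 * ||A^T y||_inf``,
which scales with the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .roi import ValidationError

CLASS_ORDER = ("mass", "normal")


@dataclass(frozen=True)
class SolverConfig:
    """Proximal-gradient solver settings.

    ``lam`` is the l1 weight; ``None`` selects ``lam_scale * ||A^T y||_inf``
    per query.  Convergence is declared when the relative objective change
    drops below ``tol``.
    """

    lam: float | None = None
    lam_scale: float = 0.01
    max_iter: int = 1000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam < 0:
            raise ValidationError("lam: must be >= 0")
        if self.lam_scale <= 0:
            raise ValidationError("lam_scale: must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter: must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol: must be > 0")


@dataclass
class Dictionary:
    """Unit-norm atoms with per-atom class labels and train-time scaling.

    ``atoms`` is d x n with the mass block first; ``mean_``/``scale_`` are
    the per-feature standardization statistics of the training set, applied
    to test vectors before coding.
    """

    atoms: np.ndarray
    atom_class: np.ndarray
    mean_: np.ndarray = None  # type: ignore[assignment]
    scale_: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        self.atom_class = np.asarray(self.atom_class, dtype=object)
        if self.atoms.ndim != 2:
            raise ValidationError("atoms: expected a d x n matrix")
        if self.atom_class.shape != (self.atoms.shape[1],):
            raise ValidationError("atom_class: length must equal atom count")
        d = self.atoms.shape[0]
        if self.mean_ is None:
            self.mean_ = np.zeros(d)
        if self.scale_ is None:
            self.scale_ = np.ones(d)
        self.mean_ = np.asarray(self.mean_, dtype=float)
        self.scale_ = np.asarray(self.scale_, dtype=float)

    @property
    def d(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    def n_per_class(self) -> dict[str, int]:
        return {c: int((self.atom_class == c).sum()) for c in CLASS_ORDER}

    def class_mask(self, cls: str) -> np.ndarray:
        return np.asarray(self.atom_class == cls)

    def transform(self, y: np.ndarray) -> np.ndarray:
        """Apply the stored train-time standardization to a test vector."""
        return (np.asarray(y, dtype=float) - self.mean_) / self.scale_


@dataclass
class SparseSolution:
    """Coefficients of one sparse code plus solver diagnostics."""

    coefficients: np.ndarray
    iterations: int
    residual_norm: float
    lam: float
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


def build_dictionary(X: np.ndarray, labels) -> Dictionary:
    """Stack training vectors into a two-class dictionary.

    Features are z-scored with the training statistics (zero-variance
    features get unit scale), then every column is l2-normalized.  Mass
    atoms come first; sample order within each class is preserved.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if X.ndim != 2 or labels.shape != (X.shape[0],):
        raise ValidationError("features: X must be n x d with n labels")
    for cls in CLASS_ORDER:
        if not np.any(labels == cls):
            raise ValidationError(f"features: class {cls!r} is empty")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - mean) / scale
    order = np.concatenate([np.flatnonzero(labels == c) for c in CLASS_ORDER])
    atoms = Z[order].T.copy()
    norms = np.linalg.norm(atoms, axis=0)
    atoms /= np.where(norms > 0, norms, 1.0)
    return Dictionary(atoms, labels[order], mean, scale)


def _default_lams(A: np.ndarray, Y: np.ndarray, cfg: SolverConfig
                  ) -> np.ndarray:
    if cfg.lam is not None:
        return np.full(Y.shape[1], float(cfg.lam))
    return cfg.lam_scale * np.max(np.abs(A.T @ Y), axis=0, initial=0.0)


def fista(A: np.ndarray, Y: np.ndarray, lams: np.ndarray,
          max_iter: int, tol: float
          ) -> tuple[np.ndarray, int, np.ndarray, bool]:
    """Batched FISTA for ``0.5||A x - y||^2 + lam ||x||_1`` per column of Y.

    Returns (X, iterations, final objectives, converged).
    """
    n = A.shape[1]
    m = Y.shape[1]
    if n == 0 or m == 0:
        return np.zeros((n, m)), 0, np.zeros(m), True
    gram_norm = np.linalg.norm(A, 2) ** 2
    step = 1.0 / max(gram_norm, 1e-12)

    # The objective is separable across columns, so converged columns are
    # frozen and dropped from the working set.
    X_out = np.zeros((n, m))
    obj_out = 0.5 * (Y ** 2).sum(axis=0)
    active = np.arange(m)
    Ya, la = Y, lams
    X = np.zeros((n, m))
    Z = X.copy()
    t = 1.0
    AtY = A.T @ Ya
    obj = obj_out.copy()
    it = 0
    for it in range(1, max_iter + 1):
        grad = A.T @ (A @ Z) - AtY
        X_new = Z - step * grad
        thresh = step * la
        X_new = np.sign(X_new) * np.maximum(np.abs(X_new) - thresh, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Z = X_new + ((t - 1.0) / t_new) * (X_new - X)
        X, t = X_new, t_new
        R = A @ X - Ya
        new_obj = 0.5 * (R ** 2).sum(axis=0) + la * np.abs(X).sum(axis=0)
        done = np.abs(obj - new_obj) <= tol * np.maximum(np.abs(obj), 1e-12)
        obj = new_obj
        if done.any():
            X_out[:, active[done]] = X[:, done]
            obj_out[active[done]] = obj[done]
            keep = ~done
            active = active[keep]
            if active.size == 0:
                return X_out, it, obj_out, True
            X, Z, Ya, la, obj = (X[:, keep], Z[:, keep], Ya[:, keep],
                                 la[keep], obj[keep])
            AtY = A.T @ Ya
    X_out[:, active] = X
    obj_out[active] = obj
    return X_out, it, obj_out, False


def sparse_code(D: Dictionary, y: np.ndarray,
                cfg: SolverConfig | None = None) -> SparseSolution:
    """Sparse-code one (already standardized) vector against the dictionary.

    On non-convergence the best iterate is returned with
    ``converged=False`` rather than raising.
    """
    cfg = cfg or SolverConfig()
    y = np.asarray(y, dtype=float)
    if y.shape != (D.d,):
        raise ValidationError(
            f"y: expected length {D.d}, got {y.shape}")
    Y = y[:, None]
    lams = _default_lams(D.atoms, Y, cfg)
    X, it, obj, converged = fista(D.atoms, Y, lams, cfg.max_iter, cfg.tol)
    x = X[:, 0]
    resid = float(np.linalg.norm(D.atoms @ x - y))
    return SparseSolution(x, it, resid, float(lams[0]), converged,
                          {"objective": float(obj[0])})


def sparse_code_batch(D: Dictionary, Y: np.ndarray,
                      cfg: SolverConfig | None = None
                      ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Code many standardized vectors at once.

    ``Y`` is d x m; returns (coefficients n x m, per-column lambdas,
    converged flag).
    """
    cfg = cfg or SolverConfig()
    Y = np.asarray(Y, dtype=float)
    lams = _default_lams(D.atoms, Y, cfg)
    X, _, _, converged = fista(D.atoms, Y, lams, cfg.max_iter, cfg.tol)
    return X, lams, converged


def class_residual(D: Dictionary, y: np.ndarray, sol: SparseSolution,
                   cls: str) -> float:
    """``||y - A delta_cls(x)||_2`` using only the class's coefficients."""
    if cls not in CLASS_ORDER:
        raise ValidationError(f"class: {cls!r} not in {CLASS_ORDER}")
    x = np.where(D.class_mask(cls), sol.coefficients, 0.0)
    return float(np.linalg.norm(np.asarray(y, dtype=float) - D.atoms @ x))


def classify_single(D: Dictionary, y: np.ndarray,
                    cfg: SolverConfig | None = None) -> str:
    """Single-dictionary SRC decision; ties go to normal."""
    yt = D.transform(y)
    sol = sparse_code(D, yt, cfg)
    r_mass = class_residual(D, yt, sol, "mass")
    r_normal = class_residual(D, yt, sol, "normal")
    return "mass" if r_mass < r_normal else "normal"
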