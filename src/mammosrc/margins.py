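"""Margin-type-specific dictionary configuration with score-level fusion.

Treating all breast masses as one positive class inflates the diversity of
the mass sub-dictionary and hurts the sparsity of its codes.  Instead, one
two-class dictionary is learned per margin type: the mass block of
dictionary ``t`` holds only masses of margin type ``t``, the normal block
holds an equally sized, seeded random sample of normal-tissue vectors
(balancing the classes), and FDDL is run on each dictionary separately.

At test time the query is sparse-coded against every margin dictionary and
the class residuals are fused by summation:

    Res_i = sum_t || y - D_t delta_i(x_t) ||_2 ,   i in {mass, normal},

with the decision ``argmin_i Res_i`` (ties to normal) and the confidence
``Res_normal - Res_mass`` (larger = more mass-like).

The conventional single-dictionary configuration is the special case where
every mass is assigned one pooled pseudo-margin, so both configurations
share this implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import FeatureSet
from .fddl import FDDLParams, LearnedDictionary, fddl_learn
from .roi import MARGIN_TYPES, ValidationError
from .sparse import SolverConfig, SparseSolution, sparse_code_batch

logger = logging.getLogger(__name__)

POOLED = "pooled"


@dataclass
class MarginModel:
    """T learned margin dictionaries plus shared feature standardization."""

    dictionaries: dict[str, LearnedDictionary]
    mean_: np.ndarray
    scale_: np.ndarray
    solver_cfg: SolverConfig
    fddl_params: FDDLParams
    seed: int
    negative_indices: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def T(self) -> int:
        return len(self.dictionaries)

    @property
    def margins(self) -> list[str]:
        return list(self.dictionaries)

    @property
    def d(self) -> int:
        return self.mean_.shape[0]

    def transform(self, Y: np.ndarray) -> np.ndarray:
        return (np.asarray(Y, dtype=float) - self.mean_) / self.scale_


@dataclass
class ClassificationResult:
    """Fused-residual decision for one query."""

    res_mass: float
    res_normal: float
    predicted: str
    confidence: float
    solutions: dict[str, SparseSolution] = field(default_factory=dict)


def _margin_order(margins_present) -> list[str]:
    canonical = [m for m in MARGIN_TYPES if m in margins_present]
    extra = sorted(m for m in margins_present if m not in MARGIN_TYPES)
    return canonical + extra


def build_margin_model(train: FeatureSet,
                       fddl_params: FDDLParams | None = None,
                       solver_cfg: SolverConfig | None = None,
                       seed: int = 0,
                       pool_margins: bool = False) -> MarginModel:
    """Assemble and learn the per-margin dictionaries from training data.

    For each margin type present, ``min(n_normal, n_mass(t))`` normal
    vectors are drawn once, without replacement, from the normal pool
    (seeded), and FDDL is run on the balanced two-class sample.  Margin
    types absent from the training data are skipped with a warning.  With
    ``pool_margins=True`` all masses form a single pooled dictionary — the
    conventional single-dictionary configuration.
    """
    fddl_params = fddl_params or FDDLParams()
    solver_cfg = solver_cfg or SolverConfig()
    labels = train.labels
    mass_idx = np.flatnonzero(labels == "mass")
    normal_idx = np.flatnonzero(labels == "normal")
    if mass_idx.size == 0:
        raise ValidationError("train: no mass samples")
    if normal_idx.size == 0:
        raise ValidationError("train: no normal samples")

    mean = train.X.mean(axis=0)
    scale = train.X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (train.X - mean) / scale

    if pool_margins:
        groups = {POOLED: mass_idx}
    else:
        mass_margins = train.margins[mass_idx]
        present = {m for m in mass_margins if m is not None}
        unlabelled = int(sum(m is None for m in mass_margins))
        if unlabelled:
            logger.warning("%d mass samples without margin labels are "
                           "excluded from dictionary construction",
                           unlabelled)
        if not present:
            raise ValidationError("train: no margin-labelled mass samples")
        groups = {t: mass_idx[np.asarray([m == t for m in mass_margins])]
                  for t in _margin_order(present)}

    rng = np.random.default_rng(seed)
    dictionaries: dict[str, LearnedDictionary] = {}
    negatives: dict[str, np.ndarray] = {}
    for t, idx_t in groups.items():
        if idx_t.size == 0:  # pragma: no cover - filtered above
            logger.warning("margin %s: no training samples, skipped", t)
            continue
        n_neg = min(normal_idx.size, idx_t.size)
        neg = rng.choice(normal_idx, size=n_neg, replace=False)
        child_seed = int(rng.integers(0, 2**31))
        data = {"mass": Z[idx_t].T, "normal": Z[neg].T}
        logger.info("margin %s: %d mass + %d normal source samples",
                    t, idx_t.size, n_neg)
        dictionaries[t] = fddl_learn(data, fddl_params, seed=child_seed)
        negatives[t] = np.sort(neg)
    return MarginModel(dictionaries, mean, scale, solver_cfg, fddl_params,
                       seed, negatives)


def per_dictionary_residuals(model: MarginModel, Y: np.ndarray
                             ) -> dict[str, dict]:
    """Code standardized queries against every dictionary.

    ``Y`` is d x m (already standardized).  Returns, per margin, the code
    matrix and both class residual vectors.
    """
    out: dict[str, dict] = {}
    for t, ld in model.dictionaries.items():
        D = ld.dictionary
        X, lams, _ = sparse_code_batch(D, Y, model.solver_cfg)
        res = {}
        for cls in ("mass", "normal"):
            sel = D.class_mask(cls)
            recon = D.atoms[:, sel] @ X[sel]
            res[cls] = np.linalg.norm(Y - recon, axis=0)
        out[t] = {"codes": X, "res_mass": res["mass"],
                  "res_normal": res["normal"], "lams": lams}
    return out


def fused_residuals_batch(model: MarginModel, Y_raw: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Fused residual sums for raw queries (rows = samples)."""
    Y = model.transform(np.atleast_2d(Y_raw)).T
    per_dict = per_dictionary_residuals(model, Y)
    m = Y.shape[1]
    res_mass = np.zeros(m)
    res_normal = np.zeros(m)
    for t in per_dict:
        res_mass += per_dict[t]["res_mass"]
        res_normal += per_dict[t]["res_normal"]
    return res_mass, res_normal, per_dict


def fused_residuals(model: MarginModel, y: np.ndarray
                    ) -> tuple[float, float]:
    """``(Res_mass, Res_normal)`` for a single raw query vector."""
    y = np.asarray(y, dtype=float)
    if y.shape != (model.d,):
        raise ValidationError(f"y: expected length {model.d}, got {y.shape}")
    rm, rn, _ = fused_residuals_batch(model, y[None, :])
    return float(rm[0]), float(rn[0])


def classify(model: MarginModel, y: np.ndarray) -> ClassificationResult:
    """Fused-residual decision with confidence ``Res_normal - Res_mass``."""
    y = np.asarray(y, dtype=float)
    if y.shape != (model.d,):
        raise ValidationError(f"y: expected length {model.d}, got {y.shape}")
    rm, rn, per_dict = fused_residuals_batch(model, y[None, :])
    res_mass, res_normal = float(rm[0]), float(rn[0])
    predicted = "mass" if res_mass < res_normal else "normal"
    solutions = {}
    for t, rec in per_dict.items():
        x = rec["codes"][:, 0]
        D = model.dictionaries[t].dictionary
        resid = float(np.linalg.norm(
            D.atoms @ x - model.transform(y)))
        solutions[t] = SparseSolution(x, -1, resid, float(rec["lams"][0]))
    return ClassificationResult(res_mass, res_normal, predicted,
                                res_normal - res_mass, solutions)


def predict_batch(model: MarginModel, X_raw: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized classification of raw feature rows.

    Returns (res_mass, res_normal, confidence, predicted labels).
    """
    rm, rn, _ = fused_residuals_batch(model, X_raw)
    conf = rn - rm
    pred = np.where(rm < rn, "mass", "normal").astype(object)
    return rm, rn, conf, pred
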