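"""Evaluation: sparsity concentration, ROC/AUC, and cross-validation.

The sparsity concentration in the true class (SCTC) of a sparse code is the
fraction of its l1 mass carried by the atoms of the sample's true class,

    SCTC(x) = ||delta_true(x)||_1 / ||x||_1  in [0, 1],

and quantifies how well a dictionary configuration concentrates a sample's
representation on the correct class.  Classification performance is the
rank-based area under the ROC curve of the fused-residual confidence.  The
cross-validation harness evaluates both dictionary configurations — the
margin-specific one and the conventional pooled single dictionary — on the
same stratified folds, repeated over independent runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dataset import FeatureSet
from .fddl import FDDLParams
from .margins import (POOLED, build_margin_model, fused_residuals_batch,
                      per_dictionary_residuals)
from .roi import ValidationError
from .sparse import SolverConfig

CONFIGURATIONS = ("margin_specific", "single")


def sctc(coefficients: np.ndarray, true_selector: np.ndarray) -> float:
    """Sparsity concentration in the true class of one sparse code.

    ``true_selector`` is a boolean mask over the coefficients marking the
    true class's atoms.  Returns 0 when the code is all-zero.
    """
    x = np.asarray(coefficients, dtype=float)
    sel = np.asarray(true_selector, dtype=bool)
    if sel.shape != x.shape:
        raise ValidationError("true_selector: shape must match coefficients")
    total = np.abs(x).sum()
    if total == 0:
        return 0.0
    return float(np.abs(x[sel]).sum() / total)


def roc_auc(confidences, labels) -> float:
    """Rank-based AUC of mass-vs-normal confidences (ties count half)."""
    labels = np.asarray(labels, dtype=object)
    confidences = np.asarray(confidences, dtype=float)
    y = (labels == "mass").astype(int)
    if y.min() == y.max():
        raise ValidationError("labels: both classes must be present")
    return float(roc_auc_score(y, confidences))


@dataclass
class EvalReport:
    """Cross-validation results for both dictionary configurations."""

    auc: dict[str, list[list[float]]]          # config -> runs x folds
    mean_auc: dict[str, float]
    sctc_per_margin: dict[str, dict[str, float]]   # config -> margin -> mean
    n_runs: int
    n_folds: int
    seed: int
    run_seeds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "mean_auc": self.mean_auc,
            "sctc_per_margin": self.sctc_per_margin,
            "n_runs": self.n_runs,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "run_seeds": self.run_seeds,
        }


def _strata(fs: FeatureSet) -> np.ndarray:
    return np.array([m if (lab == "mass" and m is not None) else lab
                     for lab, m in zip(fs.labels, fs.margins)], dtype=object)


def _fold_iter(fs: FeatureSet, k: int, run_seed: int):
    strata = _strata(fs)
    _, counts = np.unique(strata, return_counts=True)
    if counts.min() < k:
        # Margin strata too small for k folds: stratify by class only.
        strata = fs.labels.astype(str)
        _, counts = np.unique(strata, return_counts=True)
        if counts.min() < k:
            raise ValidationError(
                f"dataset: smallest class has {counts.min()} samples, "
                f"cannot stratify into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=run_seed)
    yield from skf.split(fs.X, strata.astype(str))


def _mass_sctc(model, test: FeatureSet, single: bool) -> dict[str, list]:
    """SCTC per margin for mass test samples.

    For the margin-specific configuration each mass sample is coded against
    its own margin's dictionary; for the pooled configuration against the
    single dictionary.  The true class is always the mass atom block.
    """
    out: dict[str, list] = {}
    mass_rows = np.flatnonzero(test.labels == "mass")
    if mass_rows.size == 0:
        return out
    Z = model.transform(test.X[mass_rows]).T
    margins = test.margins[mass_rows]
    if single:
        per_dict = per_dictionary_residuals(model, Z)
        codes = per_dict[POOLED]["codes"]
        sel = model.dictionaries[POOLED].dictionary.class_mask("mass")
        for j in range(mass_rows.size):
            m = margins[j]
            out.setdefault(m, []).append(sctc(codes[:, j], sel))
        return out
    for t in model.margins:
        cols = np.flatnonzero(np.asarray([m == t for m in margins]))
        if cols.size == 0:
            continue
        per_dict = per_dictionary_residuals(model, Z[:, cols])
        codes = per_dict[t]["codes"]
        sel = model.dictionaries[t].dictionary.class_mask("mass")
        out[t] = [sctc(codes[:, j], sel) for j in range(cols.size)]
    return out


def cross_validate(fs: FeatureSet,
                   fddl_params: FDDLParams | None = None,
                   solver_cfg: SolverConfig | None = None,
                   k: int = 10, runs: int = 30, seed: int = 0) -> EvalReport:
    """Stratified k-fold cross-validation repeated over independent runs.

    Each run reshuffles the stratified folds and redraws the balanced
    negative samples (via the run seed).  Every held-out sample is scored
    exactly once per run, under both dictionary configurations trained on
    the same folds.
    """
    if k < 2:
        raise ValidationError("k: must be >= 2")
    if runs < 1:
        raise ValidationError("runs: must be >= 1")
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(runs)]

    auc = {c: [] for c in CONFIGURATIONS}
    sctc_acc: dict[str, dict[str, list]] = {c: {} for c in CONFIGURATIONS}
    for run_seed in run_seeds:
        fold_auc = {c: [] for c in CONFIGURATIONS}
        for f, (tr, te) in enumerate(_fold_iter(fs, k, run_seed)):
            train, test = fs.subset(tr), fs.subset(te)
            fold_seed = (run_seed + 7919 * (f + 1)) % 2**31
            for config in CONFIGURATIONS:
                model = build_margin_model(
                    train, fddl_params, solver_cfg, seed=fold_seed,
                    pool_margins=(config == "single"))
                _, _, conf, _ = _predict(model, test)
                fold_auc[config].append(roc_auc(conf, test.labels))
                for m, vals in _mass_sctc(model, test,
                                          config == "single").items():
                    sctc_acc[config].setdefault(m, []).extend(vals)
        for config in CONFIGURATIONS:
            auc[config].append(fold_auc[config])

    mean_auc = {c: float(np.mean(auc[c])) for c in CONFIGURATIONS}
    sctc_per_margin = {
        c: {m: float(np.mean(v)) for m, v in sctc_acc[c].items()
            if m is not None}
        for c in CONFIGURATIONS}
    return EvalReport(auc, mean_auc, sctc_per_margin, runs, k, seed,
                      run_seeds)


def _predict(model, test: FeatureSet):
    rm, rn, _ = fused_residuals_batch(model, test.X)
    conf = rn - rm
    pred = np.where(rm < rn, "mass", "normal").astype(object)
    return rm, rn, conf, pred
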