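"""Model/Results facade over the margin-dictionary pipeline.

``MassMarginSRC`` holds the training data and hyperparameters;
``fit(seed)`` learns the dictionaries and returns a
``MassMarginSRCResults`` object carrying the fitted
:class:`~mammosrc.margins.MarginModel`, prediction methods and a
``summary()`` table of the learned configuration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import FeatureSet
from .fddl import FDDLParams
from .margins import (ClassificationResult, MarginModel, build_margin_model,
                      classify, predict_batch)
from .sparse import SolverConfig


class MassMarginSRC:
    """Margin-specific sparse representation classifier.

    Parameters
    ----------
    data : FeatureSet
        Training feature vectors with class labels and (for masses) margin
        annotations.
    fddl_params, solver_cfg : optional
        Hyperparameters of the dictionary learning and the l1 solver.
    pool_margins : bool
        If True, fit the conventional single (pooled) dictionary instead of
        the per-margin configuration.
    """

    def __init__(self, data: FeatureSet,
                 fddl_params: FDDLParams | None = None,
                 solver_cfg: SolverConfig | None = None,
                 pool_margins: bool = False) -> None:
        self.data = data
        self.fddl_params = fddl_params or FDDLParams()
        self.solver_cfg = solver_cfg or SolverConfig()
        self.pool_margins = pool_margins

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MassMarginSRC":
        """Build from a feature table with id/label/margin columns."""
        return cls(FeatureSet.from_dataframe(df), **kwargs)

    def fit(self, seed: int = 0) -> "MassMarginSRCResults":
        model = build_margin_model(self.data, self.fddl_params,
                                   self.solver_cfg, seed=seed,
                                   pool_margins=self.pool_margins)
        return MassMarginSRCResults(self, model, seed)


class MassMarginSRCResults:
    """Fitted margin dictionaries with prediction and reporting methods."""

    def __init__(self, model: MassMarginSRC, margin_model: MarginModel,
                 seed: int) -> None:
        self.model = model
        self.margin_model = margin_model
        self.seed = seed

    def classify(self, y: np.ndarray) -> ClassificationResult:
        """Full fused-residual decision for one raw feature vector."""
        return classify(self.margin_model, y)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Confidence ``Res_normal - Res_mass`` per row (mass-like > 0)."""
        _, _, conf, _ = predict_batch(self.margin_model, X)
        return conf

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted labels per row."""
        return predict_batch(self.margin_model, X)[3]

    def predictions_frame(self, fs: FeatureSet) -> pd.DataFrame:
        rm, rn, conf, pred = predict_batch(self.margin_model, fs.X)
        return pd.DataFrame({"id": fs.ids, "Res_mass": rm, "Res_normal": rn,
                             "confidence": conf, "predicted": pred})

    def summary(self) -> str:
        mm = self.margin_model
        lines = [
            "Margin-specific SRC model" if not self.model.pool_margins
            else "Single-dictionary SRC model",
            "=" * 44,
            f"feature dimension      {mm.d}",
            f"dictionaries (T)       {mm.T}",
            f"training samples       {len(self.model.data)}",
            f"fit seed               {self.seed}",
            f"lambda1 / lambda2      {mm.fddl_params.lambda1} / "
            f"{mm.fddl_params.lambda2}",
            "-" * 44,
            f"{'dictionary':<18}{'mass':>6}{'normal':>8}{'objective':>12}",
        ]
        for t, ld in mm.dictionaries.items():
            counts = ld.dictionary.n_per_class()
            lines.append(f"{t:<18}{counts['mass']:>6}{counts['normal']:>8}"
                         f"{ld.final_objective:>12.4g}")
        return "\n".join(lines)
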