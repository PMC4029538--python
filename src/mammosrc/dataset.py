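"""Labelled feature-vector collections shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import CLASS_LABELS, MARGIN_TYPES, ValidationError


@dataclass
class FeatureSet:
    """A matrix of feature vectors with class and margin annotations.

    Attributes
    ----------
    X : ndarray, shape (n_samples, n_features)
    labels : ndarray of str
        ``"mass"`` or ``"normal"`` per row.
    margins : ndarray of object
        Margin type per row; ``None`` for normals and unlabelled masses.
    ids : ndarray of str
        Unique sample identifiers.
    """

    X: np.ndarray
    labels: np.ndarray
    margins: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.margins = np.asarray(self.margins, dtype=object)
        if self.X.ndim != 2:
            raise ValidationError("X: expected a 2-D sample-by-feature matrix")
        n = self.X.shape[0]
        if self.labels.shape != (n,) or self.margins.shape != (n,):
            raise ValidationError("labels/margins: length must match X rows")
        bad = set(self.labels) - set(CLASS_LABELS)
        if bad:
            raise ValidationError(f"labels: unknown values {sorted(bad)}")
        bad = {m for m in self.margins if m is not None} - set(MARGIN_TYPES)
        if bad:
            raise ValidationError(f"margins: unknown values {sorted(bad)}")
        if self.ids is None:
            self.ids = np.array([f"s{i:06d}" for i in range(n)], dtype=object)
        else:
            self.ids = np.asarray(self.ids, dtype=object)
            if self.ids.shape != (n,):
                raise ValidationError("ids: length must match X rows")
            if len(set(self.ids)) != n:
                raise ValidationError("ids: must be unique")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("X: non-finite values")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "FeatureSet":
        idx = np.asarray(idx)
        return FeatureSet(self.X[idx], self.labels[idx], self.margins[idx],
                          self.ids[idx])

    def to_dataframe(self, feature_names: list[str] | None = None
                     ) -> pd.DataFrame:
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(self.n_features)]
        df = pd.DataFrame(self.X, columns=feature_names)
        df.insert(0, "margin", [m if m is not None else "none"
                                for m in self.margins])
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureSet":
        meta = {"id", "label", "margin"}
        feat_cols = [c for c in df.columns if c not in meta]
        margins = np.array(
            [None if m in (None, "none", "") or (isinstance(m, float) and
                                                 np.isnan(m)) else m
             for m in df["margin"]], dtype=object)
        return cls(df[feat_cols].to_numpy(dtype=float),
                   df["label"].to_numpy(dtype=object),
                   margins,
                   df["id"].to_numpy(dtype=object) if "id" in df else None)
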