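"""Direct feature-space generator: structured per-margin Gaussian clusters.

Bypasses image rendering and feature extraction to produce labelled feature
vectors straight from a structured Gaussian model, one cluster per mass
margin type plus one for normal tissue.  The geometry emulates the regime
of segmented mammographic candidates:

* all masses share a common "mass appearance" mean offset and a shared
  low-rank variation subspace (a bright core looks similar whatever the
  margin);
* each margin type adds its own mean offset and its own low-rank variation
  subspace — the within-class structure that a dedicated dictionary can
  represent sparsely;
* normal-tissue vectors sit partway along the common mass direction with a
  broad isotropic spread, because the negatives of a CAD pipeline are
  false-positive candidates that already resemble masses.

A mass sample of margin ``t`` is drawn as

    x = common + mu_t + W s + B_t z + sigma_t * eps,

with ``W`` the shared subspace basis, ``B_t`` the margin subspace basis,
``s, z, eps`` standard normal.  The ``separation`` knob of
:meth:`ClusterSpec.balanced` sets the pairwise distance between margin mean
offsets and is the main difficulty control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import FeatureSet
from .roi import MARGIN_TYPES, ValidationError


@dataclass(frozen=True)
class ClusterSpec:
    """Configuration of the structured per-margin Gaussian generator.

    ``margin_means``/``margin_scales`` give each margin's mean vector and
    ambient isotropic standard deviation; ``margin_subspaces`` optionally
    maps a margin to ``(basis, sd)`` with ``basis`` of shape
    ``(dimension, rank)``; ``shared_subspace`` is a ``(basis, sd)`` pair
    applied to every mass class.  ``counts`` maps margin types and
    ``"normal"`` to sample counts.
    """

    dimension: int
    margin_means: dict = field(default_factory=dict)
    margin_scales: dict = field(default_factory=dict)
    margin_subspaces: dict = field(default_factory=dict)
    shared_subspace: tuple | None = None
    normal_mean: np.ndarray = None  # type: ignore[assignment]
    normal_scale: float = 1.0
    counts: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.dimension < 2:
            raise ValidationError("dimension: must be >= 2")
        for t, mu in self.margin_means.items():
            if t not in MARGIN_TYPES:
                raise ValidationError(f"margin_means: unknown margin {t!r}")
            if np.asarray(mu).shape != (self.dimension,):
                raise ValidationError(
                    f"margin_means[{t}]: wrong length (expected "
                    f"{self.dimension})")
        for t, s in self.margin_scales.items():
            if s <= 0:
                raise ValidationError(f"margin_scales[{t}]: must be > 0")
        for t, (basis, sd) in self.margin_subspaces.items():
            if np.asarray(basis).shape[0] != self.dimension:
                raise ValidationError(
                    f"margin_subspaces[{t}]: basis rows must equal dimension")
            if sd <= 0:
                raise ValidationError(f"margin_subspaces[{t}]: sd must be > 0")
        if self.shared_subspace is not None:
            basis, sd = self.shared_subspace
            if np.asarray(basis).shape[0] != self.dimension:
                raise ValidationError(
                    "shared_subspace: basis rows must equal dimension")
            if sd <= 0:
                raise ValidationError("shared_subspace: sd must be > 0")
        if self.normal_scale <= 0:
            raise ValidationError("normal_scale: must be > 0")
        for t, c in self.counts.items():
            if c < 1:
                raise ValidationError(f"counts[{t}]: must be >= 1")
        if set(self.margin_scales) != set(self.margin_means):
            raise ValidationError("margin_scales: keys must match margin_means")

    @classmethod
    def balanced(cls, dimension: int = 20, separation: float = 6.0,
                 scale: float = 1.0, n_per_margin: int = 100,
                 n_normal: int = 500, seed: int = 0) -> "ClusterSpec":
        """The standard benchmark geometry (see module docstring).

        Mass cluster means sit at ``(2/3) * separation * scale`` along a
        seeded common direction ``g`` plus mutually orthogonal margin
        offsets (orthogonal to ``g``) with pairwise distance
        ``separation * scale``, so ``separation`` scales the whole mass
        mean structure and is the difficulty knob.  All mass clusters share
        a rank-4 subspace of sd ``2 * scale``; each margin adds a rank-3
        subspace of sd ``2 * scale`` and ambient noise of sd
        ``0.5 * scale``.  Normals are centred at ``(separation / 3) * scale``
        along ``g`` with isotropic sd ``2 * scale``.
        """
        if dimension < 10:
            raise ValidationError(
                "dimension: balanced geometry needs dimension >= 10")
        rng = np.random.default_rng(seed)
        g = rng.standard_normal(dimension)
        g /= np.linalg.norm(g)
        # Margin directions: orthonormal, orthogonal to g.
        V = rng.standard_normal((dimension, len(MARGIN_TYPES)))
        V -= np.outer(g, g @ V)
        V, _ = np.linalg.qr(V)
        W, _ = np.linalg.qr(rng.standard_normal((dimension, 4)))
        common = (2.0 / 3.0) * separation * scale * g
        offset = separation * scale / np.sqrt(2.0)
        means, scales, subspaces, counts = {}, {}, {}, {}
        for j, t in enumerate(MARGIN_TYPES):
            means[t] = common + offset * V[:, j]
            scales[t] = 0.5 * scale
            B, _ = np.linalg.qr(rng.standard_normal((dimension, 3)))
            subspaces[t] = (B, 2.0 * scale)
            counts[t] = n_per_margin
        counts["normal"] = n_normal
        return cls(dimension=dimension, margin_means=means,
                   margin_scales=scales, margin_subspaces=subspaces,
                   shared_subspace=(W, 2.0 * scale),
                   normal_mean=(separation / 3.0) * scale * g,
                   normal_scale=2.0 * scale,
                   counts=counts, seed=seed)


def gen_feature_clusters(spec: ClusterSpec) -> FeatureSet:
    """Draw the configured clusters and return a labelled feature set.

    Deterministic under ``spec.seed``; margins are drawn in canonical
    order, normals last.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, labels, margins = [], [], []
    for t in MARGIN_TYPES:
        if t not in spec.margin_means or spec.counts.get(t, 0) == 0:
            continue
        n = spec.counts[t]
        x = np.tile(np.asarray(spec.margin_means[t], dtype=float), (n, 1))
        if spec.shared_subspace is not None:
            W, sd = spec.shared_subspace
            W = np.asarray(W, dtype=float)
            x += (sd * rng.standard_normal((n, W.shape[1]))) @ W.T
        if t in spec.margin_subspaces:
            B, sd = spec.margin_subspaces[t]
            B = np.asarray(B, dtype=float)
            x += (sd * rng.standard_normal((n, B.shape[1]))) @ B.T
        x += spec.margin_scales[t] * rng.standard_normal((n, spec.dimension))
        rows.append(x)
        labels += ["mass"] * n
        margins += [t] * n
    n_norm = spec.counts.get("normal", 0)
    if n_norm:
        mu = (np.zeros(spec.dimension) if spec.normal_mean is None
              else np.asarray(spec.normal_mean, dtype=float))
        rows.append(mu + spec.normal_scale
                    * rng.standard_normal((n_norm, spec.dimension)))
        labels += ["normal"] * n_norm
        margins += [None] * n_norm
    if not rows:
        raise ValidationError("counts: no samples requested")
    return FeatureSet(np.vstack(rows), np.array(labels, dtype=object),
                      np.array(margins, dtype=object))
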