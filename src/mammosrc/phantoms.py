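"""Synthetic mass-ROI phantoms for the five radiological margin types.

Real mammographic ROIs are crops of enhanced mammograms around segmented
mass candidates.  The phantoms emulate the aspects of those ROIs that the
downstream feature battery responds to: a hyper-dense core of controllable
contrast, a margin whose geometry matches the radiological description of
each class, and a correlated "parenchyma-like" background texture that
partially conceals the lesion.  Normal-tissue patches are background texture
only, with a pseudo-mask over the central region so mask-based features can
still be computed.

Margin recipes:

* ``circumscribed`` — smooth radial blob with a sharp, well-defined edge.
* ``obscured`` — the same blob at reduced contrast with a soft edge,
  alpha-blended into the background texture.
* ``micro_lobulated`` — blob whose boundary radius is modulated by a
  high-frequency, low-amplitude sinusoid in polar angle (small undulations).
* ``ill_defined`` — blob whose intensity falls off over a wide, blurred
  transition zone.
* ``spiculated`` — blob plus 6-14 thin radial spikes (spicules).

Every generator is a pure function of its spec (seed included): identical
specs yield bit-identical patches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .roi import MARGIN_TYPES, ROIPatch, ValidationError

_PHANTOM_KINDS = MARGIN_TYPES + ("normal",)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic ROI.

    Attributes
    ----------
    image_size : int
        Pixels per side (square patch), >= 32.
    margin_type : str
        One of the five margin types, or ``"normal"``.
    core_radius : float
        Radius of the mass core in pixels; ``4 <= core_radius <= image_size/3``.
    contrast : float
        Lesion amplitude as a fraction of the dynamic range, in ``(0, 1]``.
    background_texture_scale : float
        Correlation length (pixels) of the parenchyma-like background noise.
    seed : int
    """

    image_size: int = 64
    margin_type: str = "circumscribed"
    core_radius: float = 12.0
    contrast: float = 0.5
    background_texture_scale: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValidationError("image_size: must be >= 32")
        if self.margin_type not in _PHANTOM_KINDS:
            raise ValidationError(
                f"margin_type: {self.margin_type!r} not in {_PHANTOM_KINDS}"
            )
        if not (4 <= self.core_radius <= self.image_size / 3):
            raise ValidationError(
                "core_radius: must satisfy 4 <= core_radius <= image_size/3"
            )
        if not (0 < self.contrast <= 1):
            raise ValidationError("contrast: must be in (0, 1]")
        if self.background_texture_scale <= 0:
            raise ValidationError("background_texture_scale: must be > 0")


def _background(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Band-limited correlated noise standing in for dense parenchyma."""
    noise = rng.standard_normal((n, n))
    smooth = ndimage.gaussian_filter(noise, sigma=scale)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return 0.40 + 0.06 * smooth


def _sigmoid_edge(u: np.ndarray, width: float) -> np.ndarray:
    """Radial intensity profile: ~1 inside (u < 1), rolling off over `width`."""
    return 1.0 / (1.0 + np.exp((u - 1.0) / width))


def gen_roi(spec: PhantomSpec) -> ROIPatch:
    """Render one phantom ROI from its spec.

    Returns an :class:`~mammosrc.roi.ROIPatch` with pixels in ``[0, 1]`` and a
    connected, non-empty mask.  Deterministic: the same spec always produces
    the same patch.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    bg = _background(rng, n, spec.background_texture_scale)

    # Lesion centre jittered around the patch centre.
    c0 = (n - 1) / 2.0
    jitter = n / 16.0
    cy, cx = c0 + rng.uniform(-jitter, jitter, size=2)

    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    dy, dx = rows - cy, cols - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    r0 = float(spec.core_radius)
    kind = spec.margin_type

    if kind == "normal":
        mask = rho <= r0
        return ROIPatch(np.clip(bg, 0.0, 1.0), mask, label="normal", margin=None)

    if kind == "circumscribed":
        boundary = np.full_like(theta, r0)
        lesion = spec.contrast * _sigmoid_edge(rho / boundary, 0.05)
        mask = rho <= boundary
    elif kind == "obscured":
        boundary = np.full_like(theta, r0)
        lesion = 0.45 * spec.contrast * _sigmoid_edge(rho / boundary, 0.18)
        # Extra texture on top of the lesion emulates overlying tissue.
        veil = ndimage.gaussian_filter(rng.standard_normal((n, n)), 2.0)
        sd = veil.std()
        if sd > 0:
            veil /= sd
        lesion = lesion * (1.0 + 0.25 * veil)
        mask = rho <= r0
    elif kind == "micro_lobulated":
        n_lobes = int(rng.integers(10, 17))
        phase = rng.uniform(0, 2 * np.pi)
        boundary = r0 * (1.0 + 0.10 * np.sin(n_lobes * theta + phase))
        lesion = spec.contrast * _sigmoid_edge(rho / boundary, 0.05)
        mask = rho <= boundary
    elif kind == "ill_defined":
        boundary = np.full_like(theta, r0)
        lesion = spec.contrast * _sigmoid_edge(rho / boundary, 0.40)
        mask = rho <= r0
    elif kind == "spiculated":
        boundary = np.full_like(theta, r0)
        lesion = spec.contrast * _sigmoid_edge(rho / boundary, 0.06)
        n_spikes = int(rng.integers(6, 15))
        angles = rng.uniform(0, 2 * np.pi, size=n_spikes)
        lengths = r0 * rng.uniform(1.4, 2.0, size=n_spikes)
        widths = rng.uniform(1.0, 1.8, size=n_spikes)
        spike_mask = np.zeros((n, n), dtype=bool)
        for ang, length, width in zip(angles, lengths, widths):
            # Perpendicular distance from the spike's centre line.
            perp = np.abs(-np.sin(ang) * dx + np.cos(ang) * dy)
            along = np.cos(ang) * dx + np.sin(ang) * dy
            on_spike = (perp <= width) & (along >= 0) & (along <= length)
            taper = np.clip(1.0 - along / max(length, 1e-9), 0.0, 1.0)
            lesion = np.where(
                on_spike, np.maximum(lesion, 0.7 * spec.contrast * taper), lesion
            )
            spike_mask |= on_spike
        mask = (rho <= r0) | spike_mask
    else:  # pragma: no cover - guarded by validate()
        raise ValidationError(f"margin_type: {kind!r}")

    pixels = np.clip(bg + lesion, 0.0, 1.0)
    return ROIPatch(pixels, mask, label="mass", margin=kind)


def gen_dataset(
    n_mass_per_margin: int,
    n_normal: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[ROIPatch]:
    """Generate a labelled phantom dataset.

    Produces ``n_mass_per_margin`` mass patches for each of the five margin
    types (in canonical order) followed by ``n_normal`` normal patches.
    Per-patch seeds are derived from ``seed``, so the whole dataset is
    reproducible.
    """
    if n_mass_per_margin < 0 or n_normal < 0:
        raise ValidationError("counts: must be >= 0")
    if base_spec is None:
        base_spec = PhantomSpec()
    rng = np.random.default_rng(seed)
    patches: list[ROIPatch] = []
    for margin in MARGIN_TYPES:
        for _ in range(n_mass_per_margin):
            child = int(rng.integers(0, 2**31))
            patches.append(
                gen_roi(replace(base_spec, margin_type=margin, seed=child))
            )
    for _ in range(n_normal):
        child = int(rng.integers(0, 2**31))
        patches.append(gen_roi(replace(base_spec, margin_type="normal",
                                       seed=child)))
    return patches
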