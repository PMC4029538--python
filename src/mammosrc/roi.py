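"""Region-of-interest patches: the unit of classification.

An ROI is a small grayscale crop around a segmented mass candidate together
with the binary segmentation mask delineating the candidate.  Pixel values
live in ``[0, 1]`` regardless of the bit depth of the file they came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Radiological margin taxonomy for breast masses, in canonical order.
MARGIN_TYPES = (
    "circumscribed",
    "obscured",
    "micro_lobulated",
    "ill_defined",
    "spiculated",
)

#: Short margin codes used in manifests.
MARGIN_CODES = {
    "circumscribed": "circ",
    "obscured": "obsc",
    "micro_lobulated": "mlob",
    "ill_defined": "ill",
    "spiculated": "spic",
    None: "none",
    "none": "none",
}

MARGIN_FROM_CODE = {
    "circ": "circumscribed",
    "obsc": "obscured",
    "mlob": "micro_lobulated",
    "ill": "ill_defined",
    "spic": "spiculated",
    "none": None,
}

CLASS_LABELS = ("mass", "normal")

MIN_MASK_PIXELS = 16


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class ROIPatch:
    """A grayscale pixel grid with an aligned binary mask.

    Parameters
    ----------
    pixels : ndarray of float, shape (H, W)
        Intensities in ``[0, 1]``.
    mask : ndarray of bool, shape (H, W)
        Foreground (candidate) pixels.  Normal-tissue patches carry a
        pseudo-mask over the central region so region-based features stay
        computable.
    label : {"mass", "normal"}, optional
    margin : str, optional
        Margin type for mass patches; ``None`` for normals or unknown.
    """

    pixels: np.ndarray
    mask: np.ndarray
    label: str | None = None
    margin: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.pixels.ndim != 2:
            raise ValidationError("pixels: expected a 2-D grayscale grid")
        if self.pixels.shape != self.mask.shape:
            raise ValidationError(
                f"mask: shape {self.mask.shape} does not match pixels "
                f"{self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixels: non-finite values")
        if int(self.mask.sum()) < MIN_MASK_PIXELS:
            raise ValidationError(
                f"mask: needs at least {MIN_MASK_PIXELS} foreground pixels, "
                f"got {int(self.mask.sum())}"
            )
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValidationError(f"label: {self.label!r} not in {CLASS_LABELS}")
        if self.margin is not None and self.margin not in MARGIN_TYPES:
            raise ValidationError(
                f"margin: {self.margin!r} not in {MARGIN_TYPES}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
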