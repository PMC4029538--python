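"""The 812-dimensional feature battery computed from a segmented ROI.

Seven blocks, concatenated in fixed order:

======== ==== =======================================================
block     NF  content
======== ==== =======================================================
lbp      354  uniform LBP histograms, (P,R) in {(8,1),(8,2),(8,3)},
              59 bins each, over the mask interior and a margin band
sgld     312  13 co-occurrence statistics x 6 distances x 4 directions
rls       20  Galloway's 5 run-length statistics x 4 directions
glds      96  4 gray-level-difference statistics x 6 distances x 4 dirs
nrl        5  normalized radial length: mean, sd, area ratio,
              zero-crossing count, entropy
intensity  5  contrast measure, average gray level, sd, skewness,
              kurtosis (in-mask)
stellate  20  region-based spiculation measures (core/inner/outer)
======== ==== =======================================================

Texture statistics are computed strictly inside the mask; shape statistics
come from the mask boundary; the spiculation block compares gradient
alignment with the radial direction across three concentric regions, which
responds to spicules converging on the mass centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.feature import local_binary_pattern
from skimage.morphology import dilation, disk, erosion

from .roi import ROIPatch, ValidationError
from .texture import (compute_glcm, galloway_stats, glds_vector,
                      haralick_stats, run_length_matrix)

#: (name, length) of each block, in concatenation order.
BLOCKS = (
    ("lbp", 354),
    ("sgld", 312),
    ("rls", 20),
    ("glds", 96),
    ("nrl", 5),
    ("intensity", 5),
    ("stellate", 20),
)

FEATURE_DIM = sum(n for _, n in BLOCKS)  # 812

#: block name -> (offset, length)
BLOCK_INDEX: dict[str, tuple[int, int]] = {}
_off = 0
for _name, _n in BLOCKS:
    BLOCK_INDEX[_name] = (_off, _n)
    _off += _n
del _off, _name, _n

GLCM_DISTANCES = (1, 2, 4, 6, 8, 10)
DIRECTIONS = (0, 45, 90, 135)
LBP_CONFIGS = ((8, 1), (8, 2), (8, 3))
SGLD_LEVELS = 64
GLDS_LEVELS = 64
RLS_LEVELS = 16


def feature_names() -> list[str]:
    """Column names ``block.k`` in concatenation order."""
    return [f"{name}.{k}" for name, n in BLOCKS for k in range(n)]


@dataclass
class FeatureVector:
    """One ROI's feature vector with its named block layout."""

    values: np.ndarray
    block_index: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (FEATURE_DIM,):
            raise ValidationError(
                f"values: expected length {FEATURE_DIM}, got "
                f"{self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values: non-finite entries")

    def block(self, name: str) -> np.ndarray:
        off, n = self.block_index[name]
        return self.values[off:off + n]


# ---------------------------------------------------------------------------
# individual blocks
# ---------------------------------------------------------------------------

def _lbp_block(patch: ROIPatch) -> np.ndarray:
    """59-bin uniform LBP histograms per (P,R), over interior and margin band.

    The interior is the mask eroded by R+2 pixels and the band is the mask
    dilated by R+2 minus that interior, which emphasises texture at the mass
    margin.  Each histogram is l1-normalized; an empty interior falls back to
    the mask itself so histograms always sum to 1.
    """
    out = []
    quantized = np.round(patch.pixels * 65535).astype(np.uint16)
    for p, r in LBP_CONFIGS:
        codes = local_binary_pattern(quantized, p, r, method="nri_uniform")
        n_bins = p * (p - 1) + 3  # 59 for P=8
        selem = disk(r + 2)
        interior = erosion(patch.mask, selem)
        if not interior.any():
            interior = patch.mask
        band = dilation(patch.mask, selem) & ~interior
        if not band.any():
            band = patch.mask
        for region in (interior, band):
            hist = np.bincount(codes[region].astype(int), minlength=n_bins
                               ).astype(float)[:n_bins]
            hist /= hist.sum()
            out.append(hist)
    return np.concatenate(out)


def _sgld_block(patch: ROIPatch) -> np.ndarray:
    out = []
    for d in GLCM_DISTANCES:
        for theta in DIRECTIONS:
            out.append(haralick_stats(
                compute_glcm(patch, d, theta, SGLD_LEVELS)))
    return np.concatenate(out)


def _rls_block(patch: ROIPatch) -> np.ndarray:
    n_px = int(patch.mask.sum())
    out = []
    for theta in DIRECTIONS:
        rlm = run_length_matrix(patch, theta, RLS_LEVELS)
        out.append(galloway_stats(rlm, n_px))
    return np.concatenate(out)


def _glds_block(patch: ROIPatch) -> np.ndarray:
    out = []
    for d in GLCM_DISTANCES:
        for theta in DIRECTIONS:
            out.append(glds_vector(patch, d, theta, GLDS_LEVELS))
    return np.concatenate(out)


def boundary_radial_lengths(mask: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Ordered boundary traversal radial lengths and the mask centroid.

    Uses the longest sub-pixel iso-contour of the mask so the boundary is a
    single ordered closed walk.
    """
    cy, cx = ndimage.center_of_mass(mask)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValidationError("mask: no boundary contour found")
    contour = max(contours, key=len)
    d = np.hypot(contour[:, 0] - cy, contour[:, 1] - cx)
    return d, np.array([cy, cx])


def _nrl_block(patch: ROIPatch) -> np.ndarray:
    """Normalized radial length statistics of the mask boundary."""
    d, _ = boundary_radial_lengths(patch.mask)
    dmax = d.max()
    if dmax <= 0:
        return np.zeros(5)
    dn = d / dmax
    mean = float(dn.mean())
    sd = float(dn.std())
    # Fraction of radial mass exceeding the mean radius (roughness area).
    area_ratio = float(np.clip(dn - mean, 0, None).sum() / (len(dn) * mean))
    # Zero crossings of (d - mean) along the closed boundary walk.
    s = dn - mean
    nz = s[s != 0]
    crossings = 0
    if nz.size > 1:
        crossings = int(np.sum(np.sign(nz) != np.sign(np.roll(nz, -1))))
    hist, _ = np.histogram(dn, bins=10, range=(0.0, 1.0))
    p = hist / hist.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    return np.array([mean, sd, area_ratio, float(crossings), entropy])


def _outer_band(mask: np.ndarray, width: int = 5) -> np.ndarray:
    return dilation(mask, disk(width)) & ~mask


def _moments(vals: np.ndarray) -> tuple[float, float, float, float]:
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd == 0:
        return mu, 0.0, 0.0, 0.0
    z = (vals - mu) / sd
    return mu, sd, float((z ** 3).mean()), float((z ** 4).mean() - 3.0)


def _intensity_block(patch: ROIPatch) -> np.ndarray:
    """Contrast measure, mean, sd, skewness, excess kurtosis (in-mask)."""
    inside = patch.pixels[patch.mask]
    band = _outer_band(patch.mask)
    mu, sd, skew, kurt = _moments(inside)
    contrast = 0.0
    if band.any():
        mu_band = float(patch.pixels[band].mean())
        denom = mu + mu_band
        if denom > 0:
            contrast = (mu - mu_band) / denom
    return np.array([contrast, mu, sd, skew, kurt])


def _stellate_block(patch: ROIPatch) -> np.ndarray:
    """Region-based spiculation measures.

    Two pixel-wise maps are computed from the lightly smoothed image
    gradient: (a) the absolute cosine alignment between the gradient and the
    direction toward the mask centroid, and (b) the signed radial gradient
    component.  Spiculated masses show radially aligned gradients well
    outside the core.  Statistics are taken over three regions — core
    (radial fraction < 1/3 of the mask extent), inner (the rest of the
    mask), and outer (a 5-pixel band outside the mask): per-region means
    (6), per-region standard deviations (6), pairwise differences of the
    per-region means (6), plus the global mean and sd of map (a) (2).
    """
    smoothed = ndimage.gaussian_filter(patch.pixels, 1.0)
    gy, gx = np.gradient(smoothed)
    cy, cx = ndimage.center_of_mass(patch.mask)
    rows, cols = np.mgrid[0:patch.pixels.shape[0], 0:patch.pixels.shape[1]]
    uy, ux = cy - rows, cx - cols
    rho = np.hypot(uy, ux)
    rho_safe = np.where(rho > 0, rho, 1.0)
    uy, ux = uy / rho_safe, ux / rho_safe
    radial = gx * ux + gy * uy                     # map (b)
    gmag = np.hypot(gx, gy)
    align = np.abs(radial) / np.where(gmag > 0, gmag, 1.0)   # map (a)

    rmax = rho[patch.mask].max()
    if rmax <= 0:
        rmax = 1.0
    core = patch.mask & (rho < rmax / 3.0)
    inner = patch.mask & ~core
    outer = _outer_band(patch.mask)
    regions = (core, inner, outer)

    def stats(m: np.ndarray) -> tuple[list[float], list[float]]:
        means, sds = [], []
        for reg in regions:
            if reg.any():
                means.append(float(m[reg].mean()))
                sds.append(float(m[reg].std()))
            else:
                means.append(0.0)
                sds.append(0.0)
        return means, sds

    mean_a, sd_a = stats(align)
    mean_b, sd_b = stats(radial)

    def diffs(m: list[float]) -> list[float]:
        return [m[0] - m[1], m[1] - m[2], m[0] - m[2]]

    global_region = patch.mask | outer
    ga = align[global_region]
    return np.array(mean_a + mean_b + sd_a + sd_b + diffs(mean_a)
                    + diffs(mean_b) + [float(ga.mean()), float(ga.std())])


_BLOCK_FUNCS = {
    "lbp": _lbp_block,
    "sgld": _sgld_block,
    "rls": _rls_block,
    "glds": _glds_block,
    "nrl": _nrl_block,
    "intensity": _intensity_block,
    "stellate": _stellate_block,
}


def extract_block(patch: ROIPatch, block: str) -> np.ndarray:
    """Compute one named feature block; length matches the schema."""
    if block not in _BLOCK_FUNCS:
        raise ValidationError(
            f"block: {block!r} not in {tuple(_BLOCK_FUNCS)}")
    vec = _BLOCK_FUNCS[block](patch)
    expected = BLOCK_INDEX[block][1]
    if vec.shape != (expected,):  # pragma: no cover - internal consistency
        raise AssertionError(
            f"block {block}: produced {vec.shape[0]} values, "
            f"schema says {expected}")
    return vec


def extract_features(patch: ROIPatch) -> FeatureVector:
    """Concatenate all seven blocks into the 812-long feature vector."""
    values = np.concatenate([extract_block(patch, name)
                             for name, _ in BLOCKS])
    return FeatureVector(values, dict(BLOCK_INDEX))
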