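"""Masked texture statistics: co-occurrence, gray-level difference, run length.

All statistics are computed strictly inside the segmentation mask: a pixel
pair (or run) contributes only when every pixel involved is foreground.
Off-the-shelf co-occurrence routines operate on rectangular images, so the
masked accumulation is implemented here directly; the statistic formulas are
the classical ones.

Conventions: logarithms are base 2 with ``0 * log 0 := 0``; correlation-type
statistics are 0 when a marginal variance vanishes, so every statistic is
finite on every input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import ValidationError

#: Displacement (drow, dcol) per direction in degrees, for unit distance.
_DIRECTION_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

HARALICK_NAMES = (
    "correlation", "energy", "entropy", "inertia",
    "inverse_difference_moment", "sum_average", "sum_variance",
    "sum_entropy", "difference_energy", "difference_variance",
    "difference_entropy", "imc1", "imc2",
)

GALLOWAY_NAMES = ("short_run_emphasis", "long_run_emphasis",
                  "gray_level_nonuniformity", "run_length_nonuniformity",
                  "run_percentage")

GLDS_NAMES = ("contrast", "angular_second_moment", "entropy", "mean")


def quantize(pixels: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize in-mask intensities to ``levels`` gray levels.

    The in-mask dynamic range is stretched over the levels; constant regions
    map to level 0.  Out-of-mask pixels are marked -1.
    """
    q = np.full(pixels.shape, -1, dtype=np.int64)
    vals = pixels[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        scaled = (pixels - lo) / (hi - lo) * levels
        q[mask] = np.clip(scaled[mask].astype(np.int64), 0, levels - 1)
    else:
        q[mask] = 0
    return q


def _offset(direction: int, distance: int) -> tuple[int, int]:
    if direction not in _DIRECTION_STEPS:
        raise ValidationError(
            f"direction: {direction!r} not in {sorted(_DIRECTION_STEPS)}")
    dr, dc = _DIRECTION_STEPS[direction]
    return dr * distance, dc * distance


def _masked_pairs(q: np.ndarray, dr: int, dc: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Gray levels of all pixel pairs at displacement (dr, dc), both in-mask."""
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    ok = (a >= 0) & (b >= 0)
    return a[ok], b[ok]


@dataclass
class CooccurrenceMatrix:
    """A symmetric, normalized gray-level co-occurrence matrix."""

    probs: np.ndarray
    levels: int
    distance: int
    direction: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.levels, self.levels):
            raise ValidationError("probs: shape must be (levels, levels)")


def compute_glcm(patch, distance: int, direction: int, levels: int = 64
                 ) -> CooccurrenceMatrix:
    """Masked symmetric co-occurrence matrix, normalized to sum 1.

    Only pairs with both endpoints inside the mask are counted; each pair is
    accumulated in both orders (symmetric accumulation).  If no valid pair
    exists the matrix is all zeros.
    """
    if distance < 1:
        raise ValidationError("distance: must be >= 1")
    if levels < 2:
        raise ValidationError("levels: must be >= 2")
    dr, dc = _offset(direction, distance)
    q = quantize(patch.pixels, patch.mask, levels)
    a, b = _masked_pairs(q, dr, dc)
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T
    total = counts.sum()
    if total > 0:
        counts /= total
    return CooccurrenceMatrix(counts, levels, distance, direction)


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def haralick_stats(glcm: CooccurrenceMatrix) -> np.ndarray:
    """The 13 classical co-occurrence statistics, in fixed order.

    Order: correlation, energy, entropy, inertia, inverse difference moment,
    sum average, sum variance, sum entropy, difference energy, difference
    variance, difference entropy, and the two information measures of
    correlation.
    """
    p = glcm.probs
    g = glcm.levels
    if p.sum() == 0:
        return np.zeros(13)
    i = np.arange(g, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux, muy = float(i @ px), float(i @ py)
    sx = float(np.sqrt(((i - mux) ** 2) @ px))
    sy = float(np.sqrt(((i - muy) ** 2) @ py))

    corr = 0.0
    if sx > 0 and sy > 0:
        corr = (float((ii * jj * p).sum()) - mux * muy) / (sx * sy)
    energy = float((p ** 2).sum())
    entropy = _entropy2(p.ravel())
    inertia = float(((ii - jj) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    # Sum and difference distributions p_{x+y}, p_{|x-y|}.
    psum = np.zeros(2 * g - 1)
    np.add.at(psum, (ii + jj).astype(int).ravel(), p.ravel())
    k = np.arange(2 * g - 1, dtype=float)
    sum_avg = float(k @ psum)
    sum_var = float(((k - sum_avg) ** 2) @ psum)
    sum_ent = _entropy2(psum)

    pdiff = np.zeros(g)
    np.add.at(pdiff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    kd = np.arange(g, dtype=float)
    diff_energy = float((pdiff ** 2).sum())
    diff_mean = float(kd @ pdiff)
    diff_var = float(((kd - diff_mean) ** 2) @ pdiff)
    diff_ent = _entropy2(pdiff)

    # Information measures of correlation.
    hx, hy = _entropy2(px), _entropy2(py)
    pxy = np.outer(px, py)
    ok = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[ok] * np.log2(pxy[ok])).sum())
    okm = pxy > 0
    hxy2 = float(-(pxy[okm] * np.log2(pxy[okm])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array([corr, energy, entropy, inertia, idm, sum_avg, sum_var,
                     sum_ent, diff_energy, diff_var, diff_ent, imc1, imc2])


def glds_vector(patch, distance: int, direction: int, levels: int = 64
                ) -> np.ndarray:
    """Gray-level difference statistics at one displacement.

    Histogram of absolute quantized-level differences over in-mask pairs,
    summarised by contrast, angular second moment, entropy and mean.
    """
    if distance < 1:
        raise ValidationError("distance: must be >= 1")
    dr, dc = _offset(direction, distance)
    q = quantize(patch.pixels, patch.mask, levels)
    a, b = _masked_pairs(q, dr, dc)
    hist = np.zeros(levels)
    if a.size:
        np.add.at(hist, np.abs(a - b), 1.0)
        hist /= hist.sum()
    k = np.arange(levels, dtype=float)
    contrast = float((k ** 2) @ hist)
    asm = float((hist ** 2).sum())
    ent = _entropy2(hist)
    mean = float(k @ hist)
    return np.array([contrast, asm, ent, mean])


def run_length_matrix(patch, direction: int, levels: int = 16) -> np.ndarray:
    """Gray-level run-length matrix over maximal in-mask runs.

    A run is a maximal sequence of consecutive equal-level in-mask pixels
    along the direction's scan lines; out-of-mask pixels break runs.
    Returns counts of shape ``(levels, max_run_length)``.
    """
    dr, dc = _offset(direction, 1)
    q = quantize(patch.pixels, patch.mask, levels)
    h, w = q.shape
    # Scan-line start pixels: those with no in-grid predecessor.
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    runs: list[tuple[int, int]] = []  # (level, length)
    for r0, c0 in starts:
        r, c = r0, c0
        cur_level, cur_len = -1, 0
        while 0 <= r < h and 0 <= c < w:
            v = q[r, c]
            if v >= 0 and v == cur_level:
                cur_len += 1
            else:
                if cur_len:
                    runs.append((cur_level, cur_len))
                cur_level, cur_len = (v, 1) if v >= 0 else (-1, 0)
            r, c = r + dr, c + dc
        if cur_len:
            runs.append((cur_level, cur_len))
    max_len = max((ln for _, ln in runs), default=1)
    mat = np.zeros((levels, max_len))
    for level, ln in runs:
        mat[level, ln - 1] += 1.0
    return mat


def galloway_stats(rlm: np.ndarray, n_pixels: int) -> np.ndarray:
    """Galloway's five run-length statistics.

    Order: short-run emphasis, long-run emphasis, gray-level nonuniformity,
    run-length nonuniformity, run percentage.
    """
    n_runs = rlm.sum()
    if n_runs == 0 or n_pixels == 0:
        return np.zeros(5)
    lengths = np.arange(1, rlm.shape[1] + 1, dtype=float)
    sre = float((rlm / lengths ** 2).sum() / n_runs)
    lre = float((rlm * lengths ** 2).sum() / n_runs)
    gln = float((rlm.sum(axis=1) ** 2).sum() / n_runs)
    rln = float((rlm.sum(axis=0) ** 2).sum() / n_runs)
    rp = float(n_runs / n_pixels)
    return np.array([sre, lre, gln, rln, rp])
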