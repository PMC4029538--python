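"""File formats: ROI images, manifests, feature tables, model archives.

Images are 16-bit grayscale PNGs (masks 0/255 8-bit PNGs); tabular data is
CSV; dictionary atoms are stored as whitespace-delimited text matrices with
a ``rows cols`` header line at 17 significant digits, so a saved model
reloads bit-identically without any binary dependency.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .dataset import FeatureSet
from .fddl import FDDLParams, LearnedDictionary
from .features import FEATURE_DIM, feature_names
from .margins import MarginModel
from .roi import MARGIN_CODES, MARGIN_FROM_CODE, ROIPatch, ValidationError
from .sparse import Dictionary, SolverConfig

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class IOError_(IOError):
    """File-level failure naming the offending path."""


# ---------------------------------------------------------------------------
# ROI images
# ---------------------------------------------------------------------------

def save_roi(patch: ROIPatch, image_path, mask_path) -> None:
    """Write pixels as 16-bit grayscale PNG and mask as 0/255 PNG."""
    img = np.clip(patch.pixels, 0.0, 1.0)
    iio.imwrite(str(image_path), np.round(img * 65535).astype(np.uint16))
    iio.imwrite(str(mask_path),
                np.where(patch.mask, 255, 0).astype(np.uint8))


def load_roi(image_path, mask_path, label=None, margin=None) -> ROIPatch:
    """Read an image/mask pair; intensities are rescaled to [0, 1].

    8-bit and 16-bit grayscale are supported; RGB inputs are converted to
    luminance with a logged warning.  The mask is binarized at > 0.
    """
    try:
        img = iio.imread(str(image_path))
    except Exception as exc:
        raise IOError_(f"cannot read image {image_path}: {exc}") from exc
    try:
        mask = iio.imread(str(mask_path))
    except Exception as exc:
        raise IOError_(f"cannot read mask {mask_path}: {exc}") from exc
    if img.ndim == 3:
        logger.warning("%s: RGB input converted to luminance", image_path)
        img = (0.2126 * img[..., 0] + 0.7152 * img[..., 1]
               + 0.0722 * img[..., 2])
    if mask.ndim == 3:
        mask = mask[..., 0]
    if img.shape != mask.shape:
        raise IOError_(
            f"{mask_path}: mask shape {mask.shape} does not match image "
            f"{img.shape}")
    if np.issubdtype(img.dtype, np.integer):
        denom = float(np.iinfo(img.dtype).max)
    else:
        denom = max(float(img.max()), 1.0)
    return ROIPatch(img.astype(float) / denom, mask > 0,
                    label=label, margin=margin)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("id", "image_path", "mask_path", "label", "margin",
                    "seed")


def write_manifest(rows: list[dict], path) -> None:
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "margin": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise IOError_(f"{path}: manifest missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        raise IOError_(f"{path}: duplicate ids in manifest")
    bad = set(df["label"]) - {"mass", "normal"}
    if bad:
        raise IOError_(f"{path}: unknown labels {sorted(bad)}")
    need_margin = df[(df["label"] == "mass")
                     & (~df["margin"].isin(MARGIN_FROM_CODE))]
    if len(need_margin):
        raise IOError_(
            f"{path}: mass rows need a margin code in "
            f"{sorted(MARGIN_FROM_CODE)}")
    return df


def margin_code(margin: str | None) -> str:
    return MARGIN_CODES[margin]


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(fs: FeatureSet, path) -> None:
    """One row per ROI: id, label, margin, then the 812 named columns."""
    if fs.n_features != FEATURE_DIM:
        raise ValidationError(
            f"features: expected {FEATURE_DIM} columns, got "
            f"{fs.n_features}")
    df = fs.to_dataframe(feature_names())
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> FeatureSet:
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    expected = ["id", "label", "margin"] + feature_names()
    if list(df.columns) != expected:
        raise IOError_(
            f"{path}: header does not match the {FEATURE_DIM}-column "
            "block schema")
    return FeatureSet.from_dataframe(df)


# ---------------------------------------------------------------------------
# matrices and model archives
# ---------------------------------------------------------------------------

def write_matrix(M: np.ndarray, path) -> None:
    """Whitespace-delimited text matrix with a `rows cols` header."""
    M = np.asarray(M, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{M.shape[0]} {M.shape[1]}\n")
        for row in M:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix(path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise IOError_(f"{path}: malformed matrix header")
        rows, cols = int(header[0]), int(header[1])
        M = np.loadtxt(fh, ndmin=2)
    if M.shape != (rows, cols):
        raise IOError_(
            f"{path}: matrix shape {M.shape} does not match header "
            f"({rows}, {cols})")
    return M


def save_model(model: MarginModel, directory) -> None:
    """Persist a margin model as a text-only directory archive."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "T": model.T,
        "margins": model.margins,
        "seed": model.seed,
        "solver_cfg": {k: getattr(model.solver_cfg, k)
                       for k in ("lam", "lam_scale", "max_iter", "tol")},
        "fddl_params": {
            k: getattr(model.fddl_params, k)
            for k in ("atoms_per_class", "lambda1", "lambda2", "eta",
                      "max_iter", "tol", "coding_iter")},
        "negative_indices": {t: np.asarray(v).tolist()
                             for t, v in model.negative_indices.items()},
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    write_matrix(model.mean_[None, :], directory / "feature_mean.txt")
    write_matrix(model.scale_[None, :], directory / "feature_scale.txt")
    for t, ld in model.dictionaries.items():
        sub = directory / f"dictionary_{t}"
        sub.mkdir(exist_ok=True)
        write_matrix(ld.dictionary.atoms, sub / "atoms.txt")
        (sub / "atom_class.txt").write_text(
            "\n".join(map(str, ld.dictionary.atom_class)) + "\n")
        pd.DataFrame({"iteration": range(len(ld.objective_trace)),
                      "objective": ld.objective_trace}
                     ).to_csv(sub / "objective_trace.csv", index=False)


def load_model(directory) -> MarginModel:
    directory = Path(directory)
    meta_path = directory / "metadata.json"
    if not meta_path.exists():
        raise IOError_(f"{meta_path}: missing model metadata")
    meta = json.loads(meta_path.read_text())
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise IOError_(
            f"{meta_path}: incompatible model format version "
            f"{meta.get('format_version')} (expected {MODEL_FORMAT_VERSION})")
    solver_cfg = SolverConfig(**meta["solver_cfg"])
    fddl_params = FDDLParams(**meta["fddl_params"])
    mean = read_matrix(directory / "feature_mean.txt")[0]
    scale = read_matrix(directory / "feature_scale.txt")[0]
    dictionaries = {}
    for t in meta["margins"]:
        sub = directory / f"dictionary_{t}"
        atoms_path = sub / "atoms.txt"
        if not atoms_path.exists():
            raise IOError_(f"{atoms_path}: missing atoms file")
        atoms = read_matrix(atoms_path)
        atom_class = np.array(
            (sub / "atom_class.txt").read_text().split(), dtype=object)
        trace = pd.read_csv(sub / "objective_trace.csv")["objective"].tolist()
        dictionaries[t] = LearnedDictionary(
            Dictionary(atoms, atom_class), fddl_params, trace)
    negatives = {t: np.asarray(v, dtype=int)
                 for t, v in meta.get("negative_indices", {}).items()}
    return MarginModel(dictionaries, mean, scale, solver_cfg, fddl_params,
                       meta["seed"], negatives)
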