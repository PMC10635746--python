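"""Gray-level co-occurrence matrices and Haralick-style texture features.

A GLCM at distance ``d`` and angle ``theta`` is the joint frequency of
intensity pairs at that pixel offset, computed after uniform quantization to
``quant_levels`` gray levels.  The feature set is the classic Haralick family
(contrast, energy, entropy, homogeneity, correlation, cluster statistics,
sum/difference statistics, information measures of correlation, inverse
difference variants) — 21 scalars per matrix, aggregated across angles either
by averaging (rotation-robust, the default) or by concatenation.

Conventions: matrix indices are 0-based gray levels; ``0 * log 0 = 0``;
natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError
from .image import GrayImage

__all__ = [
    "GLCMSpec",
    "FEATURE_NAMES",
    "quantize",
    "compute_glcm",
    "haralick_features",
    "features_for_dataset",
]

_ANGLE_DEGREES = (0, 45, 90, 135)

# (drow, dcol) unit offsets in the classic texture-analysis convention:
# 0 deg pairs right, 45 deg up-right, 90 deg up, 135 deg up-left
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMSpec:
    """Co-occurrence matrix configuration.

    Parameters
    ----------
    distance : int
        Pixel offset distance, >= 1.
    angles : tuple of int
        Subset of {0, 45, 90, 135} degrees.
    quant_levels : int
        Gray levels after uniform quantization (2..L).
    symmetric : bool
        Count each pair in both directions (matrix equals its transpose).
    normalized : bool
        Divide counts so entries sum to 1 per angle.
    aggregate : str
        ``"mean"`` — average features over angles; ``"concat"`` — one feature
        column per (feature, angle).
    """

    distance: int = 1
    angles: tuple[int, ...] = _ANGLE_DEGREES
    quant_levels: int = 16
    symmetric: bool = True
    normalized: bool = True
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ParameterError(f"distance must be >= 1, got {self.distance}")
        if self.quant_levels < 2:
            raise ParameterError("quant_levels must be >= 2")
        bad = set(self.angles) - set(_ANGLE_DEGREES)
        if bad or not self.angles:
            raise ParameterError(f"angles must be a nonempty subset of {_ANGLE_DEGREES}")
        if self.aggregate not in ("mean", "concat"):
            raise ParameterError("aggregate must be 'mean' or 'concat'")


#: Canonical feature order (alphabetical), fixed across the package.
FEATURE_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "contrast",
    "correlation",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "imc1",
    "imc2",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_of_squares",
    "sum_variance",
)


def quantize(img: GrayImage, quant_levels: int) -> np.ndarray:
    """Uniformly bin intensities ``[0, L-1]`` into ``quant_levels`` levels."""
    if quant_levels > img.levels:
        raise ParameterError(
            f"quant_levels ({quant_levels}) cannot exceed image levels ({img.levels})"
        )
    return (img.pixels.astype(np.int64) * quant_levels) // img.levels


def compute_glcm(img: GrayImage, spec: GLCMSpec = GLCMSpec()) -> dict[int, np.ndarray]:
    """Co-occurrence matrix per angle, keyed by angle in degrees.

    The image is quantized to ``spec.quant_levels`` before counting.

    Raises
    ------
    ContractError
        If the image is too small to contain any pair at the offset.
    """
    q = quantize(img, spec.quant_levels)
    h, w = q.shape
    out: dict[int, np.ndarray] = {}
    for a in spec.angles:
        dr, dc = (d * spec.distance for d in _ANGLE_OFFSETS[a])
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            raise ContractError(f"no pixel pairs at distance {spec.distance}, {a} deg")
        src = q[r0:r1, c0:c1].ravel()
        dst = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        mat = np.zeros((spec.quant_levels, spec.quant_levels))
        np.add.at(mat, (src, dst), 1.0)
        if spec.symmetric:
            mat = mat + mat.T
        out[a] = mat / mat.sum() if spec.normalized else mat
    return out


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log(p) with the 0*log0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def _features_one(P: np.ndarray) -> dict[str, float]:
    """All 21 features for one normalized GLCM (0-based level indices)."""
    ng = P.shape[0]
    i = np.arange(ng, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    # sum and difference distributions p_{x+y}(k), p_{x-y}(k)
    ksum = np.arange(2 * ng - 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), P.ravel())
    kdiff = np.arange(ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), P.ravel())

    absdiff = np.abs(ii - jj)
    sqdiff = (ii - jj) ** 2

    f: dict[str, float] = {}
    f["autocorrelation"] = float((ii * jj * P).sum())
    f["contrast"] = float((sqdiff * P).sum())
    denom = sd_x * sd_y
    if denom > 1e-12:
        f["correlation"] = float(((ii - mu_x) * (jj - mu_y) * P).sum() / denom)
    else:
        # degenerate (e.g. constant image): a point-mass GLCM is treated as
        # perfectly correlated
        f["correlation"] = 1.0
    f["cluster_prominence"] = float(((ii + jj - mu_x - mu_y) ** 4 * P).sum())
    f["cluster_shade"] = float(((ii + jj - mu_x - mu_y) ** 3 * P).sum())
    f["dissimilarity"] = float((absdiff * P).sum())
    f["energy"] = float((P**2).sum())
    hxy = -float(_xlogx(P).sum())
    f["entropy"] = hxy
    f["homogeneity"] = float((P / (1.0 + sqdiff)).sum())
    f["maximum_probability"] = float(P.max())
    f["sum_of_squares"] = float(((ii - mu_x) ** 2 * P).sum())
    sum_avg = float((ksum * p_sum).sum())
    f["sum_average"] = sum_avg
    f["sum_variance"] = float(((ksum - sum_avg) ** 2 * p_sum).sum())
    f["sum_entropy"] = -float(_xlogx(p_sum).sum())
    diff_avg = float((kdiff * p_diff).sum())
    f["difference_variance"] = float(((kdiff - diff_avg) ** 2 * p_diff).sum())
    f["difference_entropy"] = -float(_xlogx(p_diff).sum())

    # information measures of correlation
    hx = -float(_xlogx(px).sum())
    hy = -float(_xlogx(py).sum())
    pxpy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log(pxpy), 0.0)
    hxy1 = -float((P * log_pxpy).sum())
    hxy2 = -float((pxpy * log_pxpy).sum())
    hmax = max(hx, hy)
    f["imc1"] = (hxy - hxy1) / hmax if hmax > 1e-12 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    f["imc2"] = float(np.sqrt(max(arg, 0.0)))

    f["inverse_difference"] = float((P / (1.0 + absdiff)).sum())
    f["inverse_difference_normalized"] = float((P / (1.0 + absdiff / ng)).sum())
    f["inverse_difference_moment_normalized"] = float((P / (1.0 + sqdiff / ng**2)).sum())
    return f


def haralick_features(
    glcm_set: dict[int, np.ndarray], spec: GLCMSpec = GLCMSpec()
) -> dict[str, float]:
    """Feature vector from per-angle normalized GLCMs.

    With ``aggregate="mean"`` the result has one entry per feature name;
    with ``"concat"`` one entry per ``name_angle`` pair.

    Raises
    ------
    ContractError
        If any matrix is not normalized (entries must sum to 1).
    """
    for a, P in glcm_set.items():
        if abs(P.sum() - 1.0) > 1e-6:
            raise ContractError(f"GLCM at {a} deg is not normalized (sum={P.sum()})")
    per_angle = {a: _features_one(np.asarray(P, dtype=np.float64)) for a, P in glcm_set.items()}
    if spec.aggregate == "concat":
        return {
            f"{name}_{a}": per_angle[a][name]
            for name in FEATURE_NAMES
            for a in sorted(per_angle)
        }
    angles = sorted(per_angle)
    return {
        name: float(np.mean([per_angle[a][name] for a in angles]))
        for name in FEATURE_NAMES
    }


def features_for_dataset(
    images: list[GrayImage], labels: list[str], spec: GLCMSpec = GLCMSpec()
) -> pd.DataFrame:
    """Feature table: one row per image, fixed column order, ``label`` last."""
    if len(images) != len(labels):
        raise ContractError(
            f"{len(images)} images vs {len(labels)} labels"
        )
    rows = []
    columns: list[str] | None = None
    for img in images:
        feats = haralick_features(compute_glcm(img, spec), spec)
        if columns is None:
            columns = list(feats)
        elif list(feats) != columns:
            raise ContractError("inconsistent feature columns across images")
        rows.append(feats)
    df = pd.DataFrame(rows, columns=columns)
    df["label"] = list(labels)
    return df
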